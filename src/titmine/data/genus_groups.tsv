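# genus -> taxonomic group used by the contamination triage.
# Groups: archea, bacteria, algae, protozoa, plant, fungi, invertebrate,
# vertebrate_fish, vertebrate_amphibians, vertebrate_mammalian,
# vertebrate_reptiles, vertebrate_birds.  Edit or extend freely.
Parus	vertebrate_birds
Taeniopygia	vertebrate_birds
Gallus	vertebrate_birds
Ficedula	vertebrate_birds
Meleagris	vertebrate_birds
Danio	vertebrate_fish
Oryzias	vertebrate_fish
Xenopus	vertebrate_amphibians
Homo	vertebrate_mammalian
Mus	vertebrate_mammalian
Meles	vertebrate_mammalian
Ovis	vertebrate_mammalian
Sciurus	vertebrate_mammalian
Anolis	vertebrate_reptiles
Chrysemys	vertebrate_reptiles
Ixodes	invertebrate
Ceratophyllus	invertebrate
Operophtera	invertebrate
Drosophila	invertebrate
Caenorhabditis	invertebrate
Populus	plant
Sorghum	plant
Quercus	plant
Fraxinus	plant
Fagus	plant
Corylus	plant
Acer	plant
Poa	plant
Arabidopsis	plant
Chlamydomonas	algae
Plasmodium	protozoa
Trypanosoma	protozoa
Haemoproteus	protozoa
Hepatozoon	protozoa
Leucocytozoon	protozoa
Saccharomyces	fungi
Candida	fungi
Aspergillus	fungi
Escherichia	bacteria
Bacillus	bacteria
Pseudomonas	bacteria
Salmonella	bacteria
Methanococcus	archea
Sulfolobus	archea
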