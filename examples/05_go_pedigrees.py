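"""GO pedigrees: all ancestor paths of a term under is_a-only versus
is_a+part_of semantics, and tissue-unique term discovery.

Every term reaches its own namespace root through is_a edges; part_of edges
can carry it into a second namespace (a transporter *activity* that is part
of a transport *process*).
"""

from titmine.ontology import parse_obo, pedigree, tissue_unique_terms

OBO = """format-version: 1.2
ontology: example

[Term]
id: GO:0008150
name: biological_process
namespace: biological_process

[Term]
id: GO:0003674
name: molecular_function
namespace: molecular_function

[Term]
id: GO:0006810
name: transport
namespace: biological_process
is_a: GO:0008150 ! biological_process

[Term]
id: GO:0005215
name: transporter activity
namespace: molecular_function
is_a: GO:0003674 ! molecular_function

[Term]
id: GO:0022857
name: transmembrane transporter activity
namespace: molecular_function
is_a: GO:0005215 ! transporter activity
relationship: part_of GO:0006810 ! transport
"""

graph = parse_obo(OBO)
for semantics in ("is_a", "is_a+part_of"):
    ped = pedigree("GO:0022857", graph, semantics)
    print(f"{semantics}: roots reached = {sorted(ped.reachable_roots)}")
    for path in ped.paths:
        print("   " + " -> ".join(path))
print("  (part_of opens the second root GO:0008150: the activity maps into "
      "the process namespace)\n")

unique = tissue_unique_terms(
    contig_go={"c_heart": {"GO:0022857"}, "c_any": {"GO:0005215"}},
    tissue_specific_sets={"heart": {"c_heart"}},
    contig_tissues={"c_heart": {"heart"},
                    "c_any": {"heart", "liver", "brain"}},
    contig_tau={"c_heart": 0.93})
print(f"heart-unique terms (attached to no contig of any other tissue): "
      f"{unique['heart']}")
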