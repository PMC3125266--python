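"""Scored microsatellite scanning: +1 per matching base, -6 per mismatch,
seed unit free; report loci with score >= 6 and >= 5 complete units.
"""

from titmine.repeats import bin_repeats, extract_flanks, scan, scan_contigs
from titmine.simulate import SimulationConfig, generate_contigs, generate_genome, plant_repeats

print("hand-scored cases:")
for seq, note in [("AC" * 5, "(AC)5: 8 matching comparisons -> score 8"),
                  ("AC" * 4, "(AC)4: score 6 but only 4 units -> rejected"),
                  (plant_repeats("T" * 30, ("AAG", 6, 1), 7)[6:24],
                   "(AAG)6 with one mismatch: 14 - 6 -> score 8")]:
    hits = scan(seq)
    got = (f"unit={hits[0].unit} units={hits[0].n_units} score={hits[0].score}"
           if hits else "no hit")
    print(f"  {note}: {got}")

cfg = SimulationConfig(seed=9, n_contigs=200,
                       planted_repeats=[("AC", 9, 0), ("AAG", 7, 0),
                                        ("AGAT", 6, 1), ("AATGG", 6, 0)])
rng = cfg.rng()
genome = generate_genome(cfg, rng)
contigs, _, truth = generate_contigs(genome, cfg, rng)
hits = scan_contigs(contigs)

print(f"\n{len(hits)} repeat loci across {cfg.n_contigs} contigs "
      f"({len(truth.planted_repeats)} planted, remainder chance background):")
print(bin_repeats(hits).to_string(index=False))

seqs = {c.id: c.sequence for c in contigs}
rec = extract_flanks(seqs[hits[0].contig_id], hits[0])
print(f"\nfirst locus with flanks for primer design: "
      f"{len(rec['left_flank'])} bp + {rec['repeat']} + "
      f"{len(rec['right_flank'])} bp (short flank: {rec['short_flank']})")
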