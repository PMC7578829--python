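"""Predict progeny diversity for one candidate breeding pair.

Each locus of a sire x dam cross has four equally likely offspring
genotypes, so expected offspring heterozygosity, transmissible allele counts
and the weak-heterozygote (AAAB) penalty all have exact closed forms.
"""

from broodmate import (pair_locus_offspring_distribution, predict_pair,
                       study_scale_fixture)

panel = study_scale_fixture(seed=1)
male = panel.males()[0].id
female = panel.females()[0].id
p = predict_pair(panel, male, female)

print(f"pair {male} x {female}")
print(f"{'locus':8s} {'H_exp':>6s} {'ar':>3s} {'weak':>5s}")
for locus, st in p.per_locus.items():
    print(f"{locus:8s} {st.H_exp:6.2f} {st.ar:3d} {str(st.weak):>5s}")
print(f"mean H {p.H_mean:.3f} | total alleles {p.ar_total} "
      f"| weak-het share {p.wh_share:.3f}")

gm = panel.individual(male).genotypes[0]
gf = panel.individual(female).genotypes[0]
print(f"\nPunnett enumeration at {panel.locus_names[0]}: "
      f"{gm} x {gf} -> {pair_locus_offspring_distribution(gm, gf)}")
print("H_exp is the heterozygote fraction of those four outcomes; "
      "'weak' marks\nloci where parents share 3 of 4 allele copies (AAAB).")
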