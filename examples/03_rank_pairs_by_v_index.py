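"""Score every possible mating with the composite v index.

v = iH * H/maxH + iar * ar/max_ar + iwh * (1 - wh/max_wh), weights
0.45 / 0.45 / 0.1: heterozygosity and allele number are rewarded relative to
the best pair in the cohort, weak heterozygotes penalised.
"""

from broodmate import enumerate_pairs, score_pairs, study_scale_fixture

panel = study_scale_fixture(seed=1)
cohort = score_pairs(enumerate_pairs(panel))
ranked = sorted(cohort, key=lambda p: -p.v)

print(f"{len(cohort)} candidate pairs "
      f"({len(panel.males())} males x {len(panel.females())} females)")
print(f"{'male':6s} {'female':6s} {'H':>6s} {'ar':>3s} {'wh':>6s} {'v':>6s}")
for p in ranked[:5]:
    print(f"{p.male_id:6s} {p.female_id:6s} {p.H_mean:6.3f} {p.ar_total:3d} "
          f"{p.wh_share:6.3f} {p.v:6.3f}")
print("...")
worst = ranked[-1]
print(f"{worst.male_id:6s} {worst.female_id:6s} {worst.H_mean:6.3f} "
      f"{worst.ar_total:3d} {worst.wh_share:6.3f} {worst.v:6.3f}")
print("\nA pair that attained the cohort maxima of H and ar with zero weak "
      "heterozygotes\nwould score v = 1; rankings guide which matings to "
      "perform.")
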