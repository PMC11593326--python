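"""Agreement between cut-point sets' active/inactive verdicts.

Compliance studies often print only the marginals (children active under
each set) and the raw percent agreement; the full 2x2 table — and hence
Cohen's kappa — is recoverable exactly. Here: boys on weekdays in a
134-child preschool cohort, Pate (58/74 active) vs Butte (44/74 active)
with 81.08% raw agreement.
"""

from accelcut import agreement_result, reconstruct_2x2

table = reconstruct_2x2(n=74, first_active_total=58, second_active_total=44,
                        percent_agreement=81.08)
res = agreement_result(table)
print("reconstructed 2x2 (Pate vs Butte, boys, weekdays):")
print(f"  both active={table.a}  pate only={table.b}  "
      f"butte only={table.c}  both inactive={table.d}")
print(f"  raw agreement {res.percent_agreement:.2f}%   "
      f"kappa {res.kappa_reported:.3f} -> {res.band}")
# kappa corrects the 81% raw agreement for chance: with 78% and 59% active
# marginals, two independent classifiers would already agree ~55% of the
# time, so the chance-corrected agreement is only 'moderate'.

zero = reconstruct_2x2(n=74, first_active_total=58, second_active_total=0,
                       percent_agreement=21.62)
zres = agreement_result(zero)
print("\nPate vs Johansson (Johansson classifies everyone inactive):")
print(f"  raw agreement {zres.percent_agreement:.2f}%   "
      f"kappa {zres.kappa:.3f} -> {zres.band}")
# A constant classifier carries no information: kappa is exactly 0 no matter
# how high or low the raw agreement is.
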