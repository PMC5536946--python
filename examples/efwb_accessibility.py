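"""Quantify relative epitope accessibility from paired microscopy / blot data.

Fourteen transfection pairs of a reference and a variant construct are
simulated with large per-experiment batch effects and 30% multiplicative
noise; the variant's epitopes are 3x more antibody-accessible.  The
ratio-of-ratios (normalized EF/WB) cancels every batch nuisance and recovers
the accessibility ratio.
"""

from nanopack.accessibility import efwb_ratio_and_pairing
from nanopack.simulate import EfwbGroundTruth, simulate_efwb_experiment

truth = EfwbGroundTruth(n_pairs=14, noise_cv=0.3,
                        accessibility={"reference": 0.2, "variant": 0.6})
ef_table, wb_table = simulate_efwb_experiment(truth, seed=24)
summary = efwb_ratio_and_pairing(ef_table, wb_table)

print("pair   EF/WB ref   EF/WB var   normalized")
for p in summary.pairs[:5]:
    print(f"{p.pair_id:>4}   {p.ratio_reference:9.3f}   {p.ratio_variant:9.3f}"
          f"   {p.normalized_ratio:10.3f}")
print("  ...")
print(f"arithmetic mean +- SEM:  {summary.mean_normalized_ratio:.2f} "
      f"+- {summary.sem_normalized_ratio:.2f}")
print(f"geometric mean:          {summary.geometric_mean_ratio:.2f}   (truth {truth.true_ratio:.1f})")
print(f"paired t-test (non-normalized ratios): t = {summary.t_statistic:.2f}, "
      f"p = {summary.p_value:.4f}")
print()
print("Raw EF/WB ratios vary wildly between experiments (batch effects), but")
print("the within-pair ratio-of-ratios is scale-free and centres on the true")
print("3-fold accessibility difference.")
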