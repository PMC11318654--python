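"""Close the loop: recover a shifted 12-LOX concentration by adaptation.

A "true" cell type is emulated by shifting the 12-LOX concentration two
ln-units (about 7.4-fold) above the generic prior median.  Pseudo-data from
that truth drive an ensemble -> scoring -> top-decile selection -> KS
adaptation run; the report says where the refitted prior landed and whether
the Bonferroni-corrected KS test flagged the shift.
"""

from aacascade import parameter_recovery_harness

report = parameter_recovery_harness(shift=2.0, n_ensemble=150, seed=3)

print(f"parameter:            {report.parameter}")
print(f"prior median (ln mM): {report.prior_mu:7.2f}")
print(f"true value  (ln mM):  {report.true_ln:7.2f}  (prior + {report.shift:.0f})")
print(f"adapted median:       {report.adapted_median_ln:7.2f}  "
      f"(refit to the top {report.n_top} of {report.n_ensemble} variants)")
print(f"moved toward truth:   {report.adapted_median_ln > report.prior_mu}")
print(f"within 1 ln-unit:     {report.recovered}")
print(f"KS flag:              D={report.ks_statistic:.3f}, p={report.p_value:.2e}, "
      f"significant={report.ks_significant} (alpha=0.01/184)")
print("\nEnzyme-concentration recovery is partial by construction: the free-AA")
print("pool is consumption-limited by the sampled COX abundance, so LOX")
print("products carry that draw as a confounder the panel cannot resolve.")
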