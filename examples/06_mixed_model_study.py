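"""Multi-sample study: mixed-model and Welch tests on MBD+/MBD- differences.

Simulates several independent samples (extracts), pools per-read insert
lengths, and fits the random-intercept model
y = mu + tau*fraction + nu_sample + eps by maximum likelihood, testing tau
with a likelihood-ratio chi-square (df=1).  Damage-parameter differences are
tested with Welch t-tests across samples.
"""

from paleombd import GenomeConfig, RunConfig, damage_param_tests, fit_mixed_model
from paleombd.pipeline import simulate_run

lengths, fracs, samples, fit_rows = [], [], [], []
for j, seed in enumerate((101, 102, 103, 104)):
    cfg = RunConfig(
        genome=GenomeConfig(nuclear_length=250_000, n_cgi=8, n_te_families=3,
                            te_copies=3, n_microbial=2, microbial_length=60_000),
        n_fragments=30_000, n_reads=15_000, seed=seed,
    )
    res = simulate_run(cfg)
    for name in ("MBD_plus", "MBD_minus"):
        for r in res["reads"][name]:
            if not r.is_duplicate and r.mq_class == "MQ25" and r.origin_class != "microbial":
                lengths.append(float(r.length))
                fracs.append(name)
                samples.append(f"s{j}")
        fit = res["fits"][name]
        fit_rows.append({"species": "simulated", "sample": f"s{j}", "fraction": name,
                         "delta_s": fit.delta_s_hat, "delta_d": fit.delta_d_hat,
                         "lambda": fit.lambda_hat})

mm = fit_mixed_model(lengths, fracs, samples)
print(f"insert length: tau_hat = {mm.tau_hat:+.1f} bp (MBD+ shift), "
      f"LRT = {mm.lrt_stat:.1f}, p = {mm.p_value:.3g}")
print(f"variance components: sample {mm.sigma2_sample:.2f}, residual {mm.sigma2_resid:.1f}")
print()
for t in damage_param_tests(fit_rows):
    print(f"{t.parameter}: Welch t = {t.t_stat:+.2f}, p = {t.p_value:.3f}, "
          f"mean MBD+ - MBD- = {t.mean_difference:+.4f}")
print()
print("The positive tau confirms the capture bias toward longer inserts; the")
print("sample variance absorbs between-extract differences so the fraction")
print("effect is tested within samples.")
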