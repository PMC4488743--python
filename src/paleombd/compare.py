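"""Statistical comparison of MBD+ and MBD- fractions across samples.

The core model is the random-intercept linear mixed model

    y_ijk = mu + tau * fraction_i + nu_j + eps_ijk,
    nu_j ~ N(0, sigma_nu^2),  eps_ijk ~ N(0, sigma^2),

fitted by maximum likelihood (not REML) so the fraction effect tau can be
tested with a likelihood-ratio chi-square on one degree of freedom against
the model without tau.  The fit profiles the likelihood over the variance
ratio theta = sigma_nu^2 / sigma^2: for fixed theta the GLS solution is
closed-form (block-diagonal covariance, Woodbury inverse per sample), and
theta is maximised on a deterministic log grid refined by golden-section
search -- no random starts, so fits are exactly reproducible.

Damage parameters (delta_s, delta_d, lambda) are compared per species with
Welch two-sample t-tests, applied only to species with at least three
samples.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MixedModelFit",
    "TTestResult",
    "EnrichmentReport",
    "fit_mixed_model",
    "damage_param_tests",
    "assemble_report",
    "build_report",
]

log = logging.getLogger(__name__)

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass
class MixedModelFit:
    mu_hat: float
    tau_hat: float
    sigma2_sample: float
    sigma2_resid: float
    loglik_full: float
    loglik_null: float
    lrt_stat: float
    p_value: float
    single_sample: bool = False

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


class _GroupedGLS:
    """Profile-likelihood machinery for one random intercept.

    Per-group sufficient statistics make each theta evaluation O(#groups).
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        self.n, self.p = X.shape
        self.stats = []
        for g in np.unique(groups):
            m = groups == g
            Xg, yg = X[m], y[m]
            self.stats.append(
                (
                    len(yg),
                    Xg.T @ Xg,
                    Xg.sum(axis=0),
                    Xg.T @ yg,
                    float(yg.sum()),
                    float(yg @ yg),
                )
            )

    def loglik(self, theta: float) -> tuple[float, np.ndarray, float]:
        A = np.zeros((self.p, self.p))
        b = np.zeros(self.p)
        yy = 0.0
        logdet = 0.0
        for n_g, XtX, Xt1, Xty, y1, ytyg in self.stats:
            c = theta / (1.0 + n_g * theta)
            A += XtX - c * np.outer(Xt1, Xt1)
            b += Xty - c * Xt1 * y1
            yy += ytyg - c * y1 * y1
            logdet += math.log1p(n_g * theta)
        beta = np.linalg.solve(A, b)
        rss = yy - 2.0 * beta @ b + beta @ A @ beta
        rss = max(rss, 1e-300)
        sigma2 = rss / self.n
        ll = -0.5 * (self.n * math.log(2.0 * math.pi * sigma2) + logdet + self.n)
        return ll, beta, sigma2

    def fit(self) -> tuple[float, float, np.ndarray, float]:
        """Maximise over theta >= 0; returns (loglik, theta, beta, sigma2)."""
        grid = np.concatenate(([0.0], np.logspace(-8, 6, 141)))
        lls = [self.loglik(t)[0] for t in grid]
        i = int(np.argmax(lls))
        if i == 0:
            best_theta = 0.0
        else:
            lo = math.log(grid[max(i - 1, 1)])
            hi = math.log(grid[min(i + 1, len(grid) - 1)])
            a, bnd = lo, hi
            c = bnd - _GOLDEN * (bnd - a)
            d = a + _GOLDEN * (bnd - a)
            fc = self.loglik(math.exp(c))[0]
            fd = self.loglik(math.exp(d))[0]
            for _ in range(60):
                if fc > fd:
                    bnd, d, fd = d, c, fc
                    c = bnd - _GOLDEN * (bnd - a)
                    fc = self.loglik(math.exp(c))[0]
                else:
                    a, c, fc = c, d, fd
                    d = a + _GOLDEN * (bnd - a)
                    fd = self.loglik(math.exp(d))[0]
            best_theta = math.exp((a + bnd) / 2.0)
            if self.loglik(best_theta)[0] < lls[0]:
                best_theta = 0.0
        ll, beta, sigma2 = self.loglik(best_theta)
        return ll, best_theta, beta, sigma2


def fit_mixed_model(
    values,
    fraction_label,
    sample_id,
) -> MixedModelFit:
    """Fit y = mu + tau*fraction + nu_sample + eps by ML and LRT-test tau.

    ``fraction_label`` must take exactly two values; tau is the effect of the
    lexicographically larger level (so with MBD_minus/MBD_plus labels tau is
    the MBD+ shift).  With a single sample the random intercept is dropped
    (plain linear model) with a warning.
    """
    y = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    frac = np.asarray(fraction_label)
    samp = np.asarray(sample_id)
    if not (len(y) == len(frac) == len(samp)):
        raise ValueError("values, fraction_label and sample_id lengths differ")
    levels = sorted(set(frac.tolist()))
    if len(levels) != 2:
        raise ValueError(f"need exactly two fraction levels, got {levels}")
    x = (frac == levels[1]).astype(float)

    single = len(set(samp.tolist())) < 2
    if single:
        log.warning("single sample: falling back to a plain linear model")
        samp = np.arange(len(y))  # every observation its own group, theta pinned at 0

    X_full = np.column_stack([np.ones(len(y)), x])
    X_null = np.ones((len(y), 1))

    full = _GroupedGLS(y, X_full, samp)
    null = _GroupedGLS(y, X_null, samp)
    if single:
        ll_f, beta_f, s2_f = full.loglik(0.0)
        th_f = 0.0
        ll_n, _, _ = null.loglik(0.0)
    else:
        ll_f, th_f, beta_f, s2_f = full.fit()
        ll_n, _, _, _ = null.fit()

    lrt = max(0.0, 2.0 * (ll_f - ll_n))
    p = float(stats.chi2.sf(lrt, df=1))
    return MixedModelFit(
        mu_hat=float(beta_f[0]),
        tau_hat=float(beta_f[1]),
        sigma2_sample=float(th_f * s2_f),
        sigma2_resid=float(s2_f),
        loglik_full=float(ll_f),
        loglik_null=float(ll_n),
        lrt_stat=float(lrt),
        p_value=p,
        single_sample=single,
    )


@dataclass
class TTestResult:
    parameter: str
    species: str
    t_stat: float
    p_value: float
    mean_plus: float
    mean_minus: float
    n: int

    @property
    def mean_difference(self) -> float:
        return self.mean_plus - self.mean_minus


def damage_param_tests(
    fits_by_sample: list[dict],
    min_samples: int = 3,
    parameters: tuple[str, ...] = ("delta_s", "delta_d", "lambda"),
) -> list[TTestResult]:
    """Welch two-sample t-tests on damage parameters, per species.

    ``fits_by_sample`` rows carry keys ``species``, ``sample``, ``fraction``
    (MBD_plus / MBD_minus) and the parameter values.  Species with fewer than
    ``min_samples`` samples per fraction are skipped with a log entry.
    """
    out: list[TTestResult] = []
    species = sorted({row["species"] for row in fits_by_sample})
    for sp in species:
        rows = [r for r in fits_by_sample if r["species"] == sp]
        for param in parameters:
            plus = [r[param] for r in rows if r["fraction"] == "MBD_plus"]
            minus = [r[param] for r in rows if r["fraction"] == "MBD_minus"]
            if len(plus) < min_samples or len(minus) < min_samples:
                log.info("species %s: <%d samples per fraction, %s test skipped", sp, min_samples, param)
                continue
            if np.allclose(plus, minus) and np.var(plus) == 0 and np.var(minus) == 0:
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(plus, minus, equal_var=False)
            out.append(
                TTestResult(
                    parameter=param,
                    species=sp,
                    t_stat=float(t),
                    p_value=float(p),
                    mean_plus=float(np.mean(plus)),
                    mean_minus=float(np.mean(minus)),
                    n=len(plus) + len(minus),
                )
            )
    return out


_FOLD_METRICS = (
    # (report key, FractionStats attribute, needs nuclear gate)
    ("mean_insert_fold", "mean_insert", True),
    ("median_insert_fold", "median_insert", True),
    ("mean_gc_fold", "mean_gc", True),
    ("cpg_per_bp_fold", "mean_cpg_per_bp", True),
    ("mtdna_share_fold", "mtdna_share_of_endogenous", False),
    ("cgi_coverage_fold", "cgi_coverage_ratio", True),
    ("te_coverage_fold", "te_coverage_ratio", True),
    ("clonality_fold", "clonality", True),
)


@dataclass
class EnrichmentReport:
    """Paired MBD+/MBD- statistics with fold changes and attached tests."""

    stats_plus: dict
    stats_minus: dict
    fold_changes: dict[str, float | None] = field(default_factory=dict)
    damage: dict = field(default_factory=dict)
    mixed_models: dict[str, dict] = field(default_factory=dict)
    t_tests: list[dict] = field(default_factory=list)
    gaps: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=_jsonable)

    def to_markdown(self) -> str:
        lines = [
            "| metric | MBD+ | MBD- | fold (MBD+/MBD-) |",
            "| --- | --- | --- | --- |",
        ]
        for key, attr, _ in _FOLD_METRICS:
            fc = self.fold_changes.get(key)
            vp = self.stats_plus.get(attr)
            vm = self.stats_minus.get(attr)
            lines.append(
                f"| {attr} | {_fmt(vp)} | {_fmt(vm)} | {_fmt(fc)} |"
            )
        for key in ("delta_s_fold", "delta_d_fold", "lambda_fold", "cpg_tpg_ratio_fold", "ms_fold"):
            if key in self.fold_changes:
                lines.append(f"| {key.removesuffix('_fold')} | | | {_fmt(self.fold_changes[key])} |")
        return "\n".join(lines)


def _fmt(v) -> str:
    if v is None:
        return "-"
    if isinstance(v, float):
        return f"{v:.4g}"
    return str(v)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "as_dict"):
        return obj.as_dict()
    if hasattr(obj, "__dict__"):
        return obj.__dict__
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _safe_fold(num: float | None, den: float | None) -> float | None:
    if num is None or den is None:
        return None
    if not (np.isfinite(num) and np.isfinite(den)) or den == 0:
        return None
    return num / den


def assemble_report(
    stats_plus,
    stats_minus,
    fit_plus=None,
    fit_minus=None,
    ratio_plus: float | None = None,
    ratio_minus: float | None = None,
    ms_plus: float | None = None,
    ms_minus: float | None = None,
    mixed_models: dict | None = None,
    t_tests=None,
) -> EnrichmentReport:
    """Fold-change report from paired per-fraction statistics.

    Fold changes are MBD+/MBD- and are emitted only when both fractions pass
    the minimum-data gates for the metric; suppressed metrics are listed in
    ``gaps``.
    """
    sp = stats_plus.as_dict() if hasattr(stats_plus, "as_dict") else dict(stats_plus)
    sm = stats_minus.as_dict() if hasattr(stats_minus, "as_dict") else dict(stats_minus)
    report = EnrichmentReport(stats_plus=sp, stats_minus=sm)

    for key, attr, needs_nuclear in _FOLD_METRICS:
        gate_ok = True
        if needs_nuclear:
            gate_ok = sp.get("reliable_nuclear", True) and sm.get("reliable_nuclear", True)
        elif attr == "mtdna_share_of_endogenous":
            gate_ok = sp.get("reliable_mito", True) and sm.get("reliable_mito", True)
        if not gate_ok:
            report.fold_changes[key] = None
            report.gaps.append(f"{key}: minimum-data gate not met")
            continue
        report.fold_changes[key] = _safe_fold(sp.get(attr), sm.get(attr))

    if fit_plus is not None and fit_minus is not None:
        report.damage = {"MBD_plus": fit_plus.as_dict(), "MBD_minus": fit_minus.as_dict()}
        report.fold_changes["delta_s_fold"] = _safe_fold(fit_plus.delta_s_hat, fit_minus.delta_s_hat)
        report.fold_changes["delta_d_fold"] = _safe_fold(fit_plus.delta_d_hat, fit_minus.delta_d_hat)
        report.fold_changes["lambda_fold"] = _safe_fold(fit_plus.lambda_hat, fit_minus.lambda_hat)
    else:
        report.gaps.append("damage fits missing")
    if ratio_plus is not None and ratio_minus is not None:
        report.fold_changes["cpg_tpg_ratio_fold"] = _safe_fold(ratio_plus, ratio_minus)
        report.damage["cpg_context_ratio"] = {"MBD_plus": ratio_plus, "MBD_minus": ratio_minus}
    if ms_plus is not None and ms_minus is not None:
        report.fold_changes["ms_fold"] = _safe_fold(ms_plus, ms_minus)
        report.damage["ms"] = {"MBD_plus": ms_plus, "MBD_minus": ms_minus}
    if mixed_models:
        report.mixed_models = {
            k: (v.as_dict() if hasattr(v, "as_dict") else dict(v)) for k, v in mixed_models.items()
        }
    if t_tests:
        report.t_tests = [t.__dict__ if hasattr(t, "__dict__") else t for t in t_tests]
    return report


def build_report(run_dir) -> EnrichmentReport:
    """Assemble the report from a pipeline run directory's JSON artifacts."""
    from pathlib import Path

    run_dir = Path(run_dir)

    def load(name):
        p = run_dir / name
        if not p.exists():
            return None
        with open(p) as fh:
            return json.load(fh)

    sp = load("MBD_plus.stats.json")
    sm = load("MBD_minus.stats.json")
    if sp is None or sm is None:
        missing = [n for n, v in (("MBD_plus", sp), ("MBD_minus", sm)) if v is None]
        report = EnrichmentReport(stats_plus=sp or {}, stats_minus=sm or {})
        report.gaps.extend(f"missing fraction: {m}" for m in missing)
        return report

    from .inference import DamageFit

    def load_fit(name):
        d = load(name)
        if d is None:
            return None
        return DamageFit(
            d["delta_s"], d["delta_d"], d["lambda"], d["residual"], d["n_sites"], d["degenerate"]
        )

    fp, fm = load_fit("MBD_plus.damage_fit.json"), load_fit("MBD_minus.damage_fit.json")
    extras = load("comparison_inputs.json") or {}
    return assemble_report(
        sp,
        sm,
        fp,
        fm,
        ratio_plus=extras.get("cpg_context_ratio", {}).get("MBD_plus"),
        ratio_minus=extras.get("cpg_context_ratio", {}).get("MBD_minus"),
        ms_plus=extras.get("ms", {}).get("MBD_plus"),
        ms_minus=extras.get("ms", {}).get("MBD_minus"),
        mixed_models=extras.get("mixed_models"),
    )
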