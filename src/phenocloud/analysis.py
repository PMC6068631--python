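"""Accuracy analysis: absolute errors against ground truth, descriptive
summaries, power regression of error vs POU, agreement statistics against a
reference method, and one-way ANOVA with pairwise comparisons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidConfigError

__all__ = [
    "PowerFit",
    "AgreementResult",
    "AnovaResult",
    "abs_errors",
    "fit_power",
    "agreement_stats",
    "one_way_anova",
    "summarize_errors",
    "run_full_evaluation",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PowerFit:
    """err = a * POU**b fitted by OLS in log-log space."""

    a: float
    b: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class AgreementResult:
    """OLS of estimates on reference plus RMSE against the 1:1 line."""

    slope: float
    intercept: float
    r_squared: float
    rmse_mm: float
    n: int


@dataclass(frozen=True)
class AnovaResult:
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    ms_between: float
    ms_within: float
    f_value: float
    p_value: float
    pairwise: pd.DataFrame | None = None


def abs_errors(measurements: pd.DataFrame, ground_truth: pd.DataFrame) -> pd.DataFrame:
    """Absolute measurement errors per object and dimension.

    ``measurements`` needs columns ``object_id``, ``dim_x``, ``dim_y``,
    ``dim_z`` (extra columns such as ``shape``, ``pou``, ``replicate`` are
    carried through); ``ground_truth`` needs ``object_id`` plus the same
    three dimension columns.  Returns long-format records with columns
    ``dimension`` and ``abs_error_mm``.
    """
    truth = ground_truth.set_index("object_id")
    missing = set(measurements["object_id"]) - set(truth.index)
    if missing:
        raise KeyError(f"no ground truth for object(s): {sorted(missing)}")
    carried = [
        c for c in measurements.columns if c not in ("dim_x", "dim_y", "dim_z")
    ]
    rows = []
    for _, m in measurements.iterrows():
        t = truth.loc[m["object_id"]]
        for dim in ("x", "y", "z"):
            rec = {c: m[c] for c in carried}
            rec["dimension"] = dim
            rec["abs_error_mm"] = abs(float(m[f"dim_{dim}"]) - float(t[f"dim_{dim}"]))
            rows.append(rec)
    return pd.DataFrame(rows)


def fit_power(pou_values, errors, zero_floor: float = 0.01) -> PowerFit:
    """Fit err = a * POU**b by least squares on log(err) vs log(POU).

    Zero errors are floored at ``zero_floor`` mm before the log transform
    (their count is logged); R^2 is that of the log-log fit.
    """
    pou = np.asarray(pou_values, dtype=float)
    err = np.asarray(errors, dtype=float)
    if pou.size != err.size:
        raise InvalidConfigError("pou_values and errors must have equal length")
    if pou.size < 3:
        raise InvalidConfigError("need at least 3 points for a power fit")
    if np.any(pou <= 0):
        raise InvalidConfigError("POU values must be positive")
    if np.any(err < 0):
        raise InvalidConfigError("errors must be non-negative")
    n_floored = int(np.sum(err < zero_floor))
    if n_floored:
        log.info("fit_power: floored %d error(s) below %g mm", n_floored, zero_floor)
    err = np.maximum(err, zero_floor)
    x, y = np.log(pou), np.log(err)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-y input is a valid edge case
        res = stats.linregress(x, y)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    return PowerFit(a=float(np.exp(res.intercept)), b=float(res.slope),
                    r_squared=r2, n=int(pou.size))


def agreement_stats(estimated, reference) -> AgreementResult:
    """Agreement between an automated estimate and a reference measurement.

    Slope/intercept/R^2 come from OLS of estimated on reference; RMSE is
    taken against the identity line (pure method difference, not residuals).
    """
    est = np.asarray(estimated, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.size != ref.size:
        raise InvalidConfigError("vectors must have equal length")
    if est.size < 3:
        raise InvalidConfigError("need at least 3 pairs")
    if np.ptp(ref) == 0:
        raise InvalidConfigError("reference has zero variance")
    res = stats.linregress(ref, est)
    rmse = float(np.sqrt(np.mean((est - ref) ** 2)))
    return AgreementResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        rmse_mm=rmse,
        n=int(est.size),
    )


def one_way_anova(groups: "dict[str, np.ndarray]", pairwise: bool = True,
                  alpha: float = 0.05) -> AnovaResult:
    """One-way fixed-effects ANOVA with optional unadjusted pairwise t-tests.

    Pairwise comparisons use the pooled within-group mean square (the
    classic least-squares-means contrast with unadjusted p-values).
    """
    if len(groups) < 2:
        raise InvalidConfigError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float).ravel() for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise InvalidConfigError(f"group {k!r} has fewer than 2 observations")
    all_values = np.concatenate(list(arrays.values()))
    grand = all_values.mean()
    n_total = all_values.size
    k = len(arrays)
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in arrays.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
    df_between, df_within = k - 1, n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        f_value = 0.0 if ms_between == 0 else np.inf
    else:
        f_value = ms_between / ms_within
    p_value = float(stats.f.sf(f_value, df_between, df_within)) if np.isfinite(f_value) else 0.0

    table = None
    if pairwise:
        rows = []
        for (name_i, vi), (name_j, vj) in combinations(arrays.items(), 2):
            diff = vi.mean() - vj.mean()
            se = np.sqrt(ms_within * (1 / vi.size + 1 / vj.size))
            t = diff / se if se > 0 else (0.0 if diff == 0 else np.inf)
            p = float(2 * stats.t.sf(abs(t), df_within)) if np.isfinite(t) else 0.0
            rows.append(
                {
                    "group_a": name_i,
                    "group_b": name_j,
                    "mean_diff": float(diff),
                    "t": float(t),
                    "p": p,
                    "significant": p < alpha,
                }
            )
        table = pd.DataFrame(rows)
    return AnovaResult(
        df_between=df_between,
        df_within=df_within,
        ss_between=float(ss_between),
        ss_within=float(ss_within),
        ms_between=float(ms_between),
        ms_within=float(ms_within),
        f_value=float(f_value),
        p_value=p_value,
        pairwise=table,
    )


def summarize_errors(records: pd.DataFrame) -> pd.DataFrame:
    """Per (dimension, shape) mean +/- sample std of absolute errors.

    Groups with a single record report std = 0 and ``single_record=True``.
    Empty groups are simply absent (a warning is emitted when the input
    itself is empty).
    """
    if records.empty:
        warnings.warn("summarize_errors: no records")
        return pd.DataFrame(
            columns=["dimension", "shape", "mean_mm", "std_mm", "n", "single_record"]
        )
    rows = []
    for (dim, shape), grp in records.groupby(["dimension", "shape"], sort=True):
        # sort so the result is bit-identical regardless of record order
        e = np.sort(grp["abs_error_mm"].to_numpy(dtype=float))
        rows.append(
            {
                "dimension": dim,
                "shape": shape,
                "mean_mm": float(e.mean()),
                "std_mm": float(e.std(ddof=1)) if e.size > 1 else 0.0,
                "n": int(e.size),
                "single_record": e.size == 1,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full synthetic evaluation


def run_full_evaluation(
    config=None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    make_plots: bool = False,
) -> dict:
    """Synthetic end-to-end experiment: generate object clouds, degrade them
    across the POU grid, measure, and analyse errors.

    Returns a dict with ``errors`` (DataFrame), ``summary``, ``power_fits``
    (per dimension), and ``anova`` (per dimension across shapes).  When
    ``out_dir`` is given, writes errors.csv, summary.csv, powerfit.csv and
    anova.txt (plus plots when requested).  Deterministic given the config
    and seed.
    """
    from .config import RunConfig  # local import to avoid a cycle
    from .objects import TrimSpec, measure_object
    from .scene import degrade_for_pou, make_object_cloud

    config = config or RunConfig()
    sim = config.simulation
    trim = TrimSpec(
        config.measurement.n_bins,
        config.measurement.trim_low_bins,
        config.measurement.trim_high_bins,
    )
    ss = np.random.SeedSequence(seed)
    records = []
    for rep, rep_seed in enumerate(ss.spawn(sim.replicates)):
        child = {name: s for name, s in zip(sim.object_specs, rep_seed.spawn(len(sim.object_specs)))}
        for name, spec in sim.object_specs.items():
            base_seed, degrade_seed = child[name].spawn(2)
            base = make_object_cloud(
                spec, sim.noise, seed=int(base_seed.generate_state(1)[0]),
                bed_margin_mm=sim.bed_margin_mm,
            )
            d_seeds = degrade_seed.spawn(len(sim.pou_values))
            for pou, d_seed in zip(sim.pou_values, d_seeds):
                cloud = degrade_for_pou(
                    base, pou, sim.degradation, seed=int(d_seed.generate_state(1)[0])
                )
                frac = config.measurement.center_fraction_per_shape.get(
                    spec.shape, config.measurement.center_fraction
                )
                m = measure_object(
                    cloud,
                    slice_width_mm=config.measurement.slice_width_mm,
                    center_fraction=frac,
                    trim=trim,
                    bottom_percentile=config.measurement.bottom_percentile,
                )
                truth = spec.true_dims
                for dim, measured, true in zip(
                    ("x", "y", "z"), (m.dim_x_mm, m.dim_y_mm, m.dim_z_mm), truth
                ):
                    records.append(
                        {
                            "object_id": name,
                            "shape": spec.shape,
                            "replicate": rep,
                            "pou": pou,
                            "dimension": dim,
                            "measured_mm": measured,
                            "truth_mm": true,
                            "abs_error_mm": abs(measured - true),
                        }
                    )
    errors = pd.DataFrame(records)
    summary = summarize_errors(errors)

    power_fits = {}
    for dim, grp in errors.groupby("dimension"):
        mean_by_pou = grp.groupby("pou")["abs_error_mm"].mean()
        power_fits[dim] = fit_power(mean_by_pou.index.to_numpy(), mean_by_pou.to_numpy())

    anova = {}
    for dim, grp in errors.groupby("dimension"):
        groups = {
            shape: g["abs_error_mm"].to_numpy() for shape, g in grp.groupby("shape")
        }
        if len(groups) >= 2 and all(v.size >= 2 for v in groups.values()):
            anova[dim] = one_way_anova(groups)

    result = {"errors": errors, "summary": summary, "power_fits": power_fits, "anova": anova}
    if out_dir is not None:
        _write_report(result, Path(out_dir), make_plots)
    return result


def _write_report(result: dict, out_dir: Path, make_plots: bool) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result["errors"].to_csv(out_dir / "errors.csv", index=False)
    result["summary"].to_csv(out_dir / "summary.csv", index=False)
    pd.DataFrame(
        [
            {"dimension": d, "a": f.a, "b": f.b, "r_squared": f.r_squared, "n": f.n}
            for d, f in result["power_fits"].items()
        ]
    ).to_csv(out_dir / "powerfit.csv", index=False)
    with open(out_dir / "anova.txt", "w") as fh:
        for dim, res in result["anova"].items():
            fh.write(
                f"dimension {dim}: F({res.df_between}, {res.df_within}) = "
                f"{res.f_value:.4f}, p = {res.p_value:.4g}\n"
                f"  SS between = {res.ss_between:.4f}, SS within = {res.ss_within:.4f}\n"
            )
            if res.pairwise is not None:
                fh.write(res.pairwise.to_string(index=False) + "\n")
    if make_plots:
        _plot_error_vs_pou(result, out_dir)


def _plot_error_vs_pou(result: dict, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    errors = result["errors"]
    for dim, grp in errors.groupby("dimension"):
        mean_by_pou = grp.groupby("pou")["abs_error_mm"].mean()
        ax.plot(mean_by_pou.index, mean_by_pou.to_numpy(), "o-", label=f"dim {dim}")
        fit = result["power_fits"][dim]
        grid = np.linspace(mean_by_pou.index.min(), mean_by_pou.index.max(), 100)
        ax.plot(grid, fit.a * grid**fit.b, "--", alpha=0.6)
    ax.set_xlabel("POU (pixel/mm)")
    ax.set_ylabel("mean absolute error (mm)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "error_vs_pou.png", dpi=120)
    plt.close(fig)
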