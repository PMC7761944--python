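"""Validation analytics for the synthetic benchmark.

Trueness/precision of each technique against the gold standard, Bland–Altman
reproducibility, repeated-scan error, and the nonparametric comparisons
(Friedman + pairwise Wilcoxon with Bonferroni adjustment; Mann–Whitney /
Kruskal–Wallis for covariates).  The statistical routines are the standard
scipy implementations; the module's substance is the pairing structure and
the benchmark orchestration around them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import RegionMask
from .errors import InvalidInputError
from .synthetic import (
    ScanNoiseSpec,
    ToothSpec,
    WearCase,
    apply_scan_noise,
    assemble,
    make_tooth,
    random_rigid_displacement,
)
from .wear import measure_wear


@dataclass
class ReproPair:
    """Two repeated measurements of the same case with one technique."""

    case_id: str
    technique_id: str
    measurement_1: float
    measurement_2: float


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def trueness_precision(diffs: pd.DataFrame) -> pd.DataFrame:
    """Robust per-technique summary of differences from the gold standard.

    ``diffs``: one column per technique, one row per case (mm³).  The median
    estimates trueness; min/max/IQR describe precision; ``max_abs`` is the
    worst individual deviation.
    """
    if diffs.shape[0] < 1 or diffs.shape[1] < 1:
        raise InvalidInputError("empty difference table")
    out = {}
    for col in diffs.columns:
        x = np.asarray(diffs[col], dtype=float)
        if len(x) == 0 or not np.isfinite(x).all():
            raise InvalidInputError(f"technique {col!r} has empty/non-finite diffs")
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        out[col] = {
            "median": med,
            "min": x.min(),
            "max": x.max(),
            "iqr": q3 - q1,
            "max_abs": np.abs(x).max(),
            "n": len(x),
        }
    return pd.DataFrame(out).T


def bland_altman(pairs: list[ReproPair]) -> dict:
    """Mean difference and 95% limits of agreement of repeated measurements."""
    if len(pairs) < 2:
        raise InvalidInputError("Bland-Altman needs at least 2 pairs")
    d = np.array([p.measurement_1 - p.measurement_2 for p in pairs])
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "mean_diff": mean,
        "sd_diff": sd,
        "loa_low": mean - 1.96 * sd,
        "loa_high": mean + 1.96 * sd,
        "max_abs_diff": float(np.abs(d).max()),
        "diffs": d,
    }


def bland_altman_plot(pairs: list[ReproPair], path) -> None:
    """Optional plot artifact (means vs differences with limits of agreement)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ba = bland_altman(pairs)
    m = np.array([(p.measurement_1 + p.measurement_2) / 2 for p in pairs])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(m, ba["diffs"], s=18)
    for y, ls in ((ba["mean_diff"], "-"), (ba["loa_low"], "--"), (ba["loa_high"], "--")):
        ax.axhline(y, ls=ls, color="k", lw=0.8)
    ax.set_xlabel("mean wear volume (mm$^3$)")
    ax.set_ylabel("difference (mm$^3$)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# hypothesis tests
# ---------------------------------------------------------------------------

def _safe_wilcoxon(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    d = np.asarray(x) - np.asarray(y)
    if np.all(d == 0):
        return 0.0, 1.0
    res = sps.wilcoxon(x, y)
    return float(res.statistic), float(res.pvalue)


def compare_techniques(
    diffs: pd.DataFrame, covariates: pd.DataFrame | None = None, alpha: float = 0.05
) -> dict:
    """Omnibus and pairwise tests on the per-case technique differences.

    ``diffs`` must be complete blocks (every case measured by every
    technique).  Pairwise Wilcoxon signed-rank p-values come with the
    Bonferroni-adjusted significance level; covariate effects (tooth type,
    crowding: Mann–Whitney; loss level: Kruskal–Wallis) are tested per
    technique when ``covariates`` is given.
    """
    if diffs.isna().any().any():
        raise InvalidInputError("incomplete blocks: NaN in the difference table")
    cols = list(diffs.columns)
    if len(cols) < 2:
        raise InvalidInputError("need at least two techniques to compare")
    arrays = [np.asarray(diffs[c], dtype=float) for c in cols]
    if all(np.allclose(a, arrays[0]) for a in arrays[1:]):
        friedman = {"statistic": 0.0, "pvalue": 1.0}
    elif len(cols) == 2:
        # Friedman needs >= 3 groups; with two techniques the omnibus test
        # degenerates to the paired signed-rank test
        stat, p = _safe_wilcoxon(arrays[0], arrays[1])
        friedman = {"statistic": stat, "pvalue": p}
    else:
        st = sps.friedmanchisquare(*arrays)
        friedman = {"statistic": float(st.statistic), "pvalue": float(st.pvalue)}

    n_pairs = len(cols) * (len(cols) - 1) // 2
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            stat, p = _safe_wilcoxon(arrays[i], arrays[j])
            rows.append(
                {
                    "a": cols[i],
                    "b": cols[j],
                    "statistic": stat,
                    "pvalue": p,
                    "p_bonferroni": min(1.0, p * n_pairs),
                    "significant": p < alpha / n_pairs,
                }
            )
    pairwise = pd.DataFrame(rows)

    covariate_tests = {}
    if covariates is not None:
        for col in cols:
            x = np.asarray(diffs[col], dtype=float)
            tests = {}
            for cov in ("tooth_type", "crowding"):
                if cov in covariates:
                    groups = [x[np.asarray(covariates[cov]) == g] for g in pd.unique(covariates[cov])]
                    groups = [g for g in groups if len(g)]
                    if len(groups) == 2:
                        r = sps.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
                        tests[cov] = {"statistic": float(r.statistic), "pvalue": float(r.pvalue)}
            if "loss_level" in covariates:
                groups = [
                    x[np.asarray(covariates["loss_level"]) == g]
                    for g in pd.unique(covariates["loss_level"])
                ]
                groups = [g for g in groups if len(g)]
                if len(groups) >= 2 and not all(
                    np.allclose(g, groups[0][0]) for g in groups
                ):
                    r = sps.kruskal(*groups)
                    tests["loss_level"] = {"statistic": float(r.statistic), "pvalue": float(r.pvalue)}
            covariate_tests[col] = tests

    return {"friedman": friedman, "pairwise": pairwise, "covariates": covariate_tests, "alpha": alpha}


# ---------------------------------------------------------------------------
# benchmark orchestration
# ---------------------------------------------------------------------------

def measure_benchmark(
    cases: list[WearCase],
    techniques: list[str],
    seed: int = 0,
    distance_threshold: float = 0.05,
) -> pd.DataFrame:
    """Wear volume per case × technique (long table with covariates)."""
    rows = []
    for k, case in enumerate(cases):
        for tech in techniques:
            meas = measure_wear(
                case.t0_model, case.t1_model, case.labels, tech,
                case.landmarks, seed=seed + k, distance_threshold=distance_threshold,
            )
            rows.append(
                {
                    "case_id": case.case_id,
                    "technique": tech,
                    "wear": meas.wear_volume,
                    "truth": case.true_removed_volume,
                    "tooth_type": case.tooth_type,
                    "loss_level": case.loss_level,
                    "pattern": case.pattern,
                    "crowding": case.crowding,
                    "rms_residual": meas.rms_residual,
                }
            )
    return pd.DataFrame(rows)


def differences_vs_gs(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot the long benchmark table to per-case (technique − GS) differences."""
    wide = table.pivot(index="case_id", columns="technique", values="wear")
    if "GS" not in wide:
        raise InvalidInputError("benchmark table lacks the GS technique")
    diffs = wide.drop(columns="GS").sub(wide["GS"], axis=0)
    cov = (
        table[table.technique == "GS"]
        .set_index("case_id")[["tooth_type", "loss_level", "pattern", "crowding"]]
        .loc[diffs.index]
    )
    return diffs, cov


def reproducibility(
    cases: list[WearCase],
    techniques: list[str] = ("GS", "CC_C"),
    seed: int = 1,
    landmark_sd: float = 0.25,
) -> list[ReproPair]:
    """Repeat each measurement from an independently perturbed initial pose.

    The meshes stay identical (same scans); the second measurement starts
    from a fresh random displacement of T1 and re-picked (re-jittered)
    coarse landmarks — the in-silico analog of the operator redoing the
    approximation and registration after a pause.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    for k, case in enumerate(cases):
        extra = random_rigid_displacement(rng)
        t1_re = case.t1_model.transformed(extra)
        lm0, lm1 = case.landmarks
        lm1_re = extra.apply(lm1) + rng.normal(0.0, landmark_sd, size=lm1.shape)
        for tech in techniques:
            m1 = measure_wear(
                case.t0_model, case.t1_model, case.labels, tech, case.landmarks, seed=seed + k
            )
            m2 = measure_wear(
                case.t0_model, t1_re, case.labels, tech, (lm0, lm1_re), seed=seed + k
            )
            pairs.append(ReproPair(case.case_id, tech, m1.wear_volume, m2.wear_volume))
    return pairs


def repeated_scan_error(
    n: int = 10,
    noise: ScanNoiseSpec = ScanNoiseSpec(),
    technique: str = "CC_C",
    seed: int = 0,
    resolution: int = 30000,
) -> dict:
    """Scanner + superimposition error on single teeth.

    Each tooth is "scanned" twice (independent noise realisations), the
    second scan randomly re-posed, the pair superimposed with the given
    technique and the occlusal part volume difference taken as the error.
    Returns the per-tooth absolute differences with median and range.

    The volume error integrates the surface noise over the occlusal part,
    so it scales with mesh density (sigma ~ area x noise_sd / sqrt(N)); the
    default resolution approximates the per-crown density of laboratory
    arch scans, which single-tooth meshes make affordable.
    """
    if n < 2:
        raise InvalidInputError("need n >= 2 teeth")
    rng = np.random.default_rng(seed)
    diffs = []
    for k in range(n):
        tooth_type = "incisor" if k % 2 == 0 else "canine"
        spec = ToothSpec(
            tooth_type=tooth_type,
            crown_height=float(rng.uniform(9.5, 11.0)),
            mesiodistal=float(rng.uniform(7.2, 8.6)),
            buccolingual=float(rng.uniform(6.4, 7.4)),
            resolution=resolution,
        )
        comp = make_tooth(spec, seed=int(rng.integers(2**31 - 1)))
        comp.name = "test_tooth"
        mesh, labels, lm = assemble([comp])
        scan1 = apply_scan_noise(mesh, dc_replace(noise, seed=int(rng.integers(2**31 - 1))))
        scan2 = apply_scan_noise(mesh, dc_replace(noise, seed=int(rng.integers(2**31 - 1))))
        pose = random_rigid_displacement(rng)
        scan2 = scan2.transformed(pose)
        labels = dict(labels)
        labels["tooth_t1"] = RegionMask("tooth_t1", np.arange(scan2.n_vertices))
        lm2 = pose.apply(lm) + rng.normal(0.0, 0.25, size=lm.shape)
        meas = measure_wear(scan1, scan2, labels, technique, (lm, lm2), seed=seed + k)
        diffs.append(abs(meas.wear_volume))
    d = np.asarray(diffs)
    return {
        "abs_differences": d,
        "median": float(np.median(d)),
        "min": float(d.min()),
        "max": float(d.max()),
    }
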