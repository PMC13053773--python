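"""The correlation study: Pearson r with exact-t p-values, Benjamini–Hochberg
FDR within declared families, percentile-bootstrap confidence intervals,
effect-size bands, sensitivity variants, and the minimum-detectable-r power
computation.

Families group the tests over which the false-discovery rate is controlled.
The default design declares one family per heatmap: joint-matched isokinetic
strength × muscle CNA, and IMTP force-time metrics × muscle CNA, each family
spanning all three running speeds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special, stats as sstats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, InvalidParameterError, UndefinedCorrelationError
from .synthetic import IMTP_VARS, SPEEDS, cna_column, iemg_column
from .types import ANKLE_MUSCLES, KNEE_MUSCLES, MUSCLES

EFFECT_BANDS = (
    (0.0, 0.1, "trivial"),
    (0.1, 0.3, "small"),
    (0.3, 0.5, "moderate"),
    (0.5, 0.7, "large"),
    (0.7, 0.9, "very large"),
    (0.9, 1.0, "nearly perfect"),
)


@dataclass(frozen=True)
class CorrelationResult:
    x_name: str
    y_name: str
    speed: float
    n_used: int
    r: float
    p_raw: float
    p_adj: float
    ci95: tuple[float, float]
    band: str
    family_id: str


@dataclass(frozen=True)
class FamilySpec:
    """One FDR family: named (x, y, speed) triples sharing a BH correction."""

    family_id: str
    pairs: tuple[tuple[str, str, float], ...]


@dataclass(frozen=True)
class PowerSpec:
    n: int
    alpha: float = 0.05
    power: float = 0.80
    detectable_r: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise InvalidParameterError("alpha must lie in (0, 1)")
        if not (0 < self.power < 1):
            raise InvalidParameterError("power must lie in (0, 1)")
        if self.n <= 3:
            raise InvalidParameterError("need n > 3 participants")


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def normality_report(x: np.ndarray) -> tuple[float, float]:
    """Shapiro–Wilk W and p (report-only; does not gate the Pearson tests)."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if not 3 <= x.size <= 5000:
        raise InvalidParameterError(f"Shapiro–Wilk needs 3 ≤ n ≤ 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise UndefinedCorrelationError("Shapiro–Wilk undefined for a constant vector")
    w, p = sstats.shapiro(x)
    return float(w), float(p)


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pearson r with the exact two-tailed p from t = r√(n−2)/√(1−r²).

    Pairs with a missing value in either variable are dropped
    (pairwise-complete); the returned ``n_used`` is the pair count actually
    correlated.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidParameterError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise UndefinedCorrelationError(f"need ≥ 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for zero variance")
    r, _ = sstats.pearsonr(x, y)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    p = 2.0 * sstats.t.sf(abs(t), n - 2)
    return r, float(min(p, 1.0)), n


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values within one family."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InvalidParameterError("p-values must lie in (0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def bootstrap_ci(x: np.ndarray, y: np.ndarray, B: int = 1999,
                 seed: int = 0, level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI for Pearson r over participant-level resamples.

    Degenerate resamples (zero variance in either variable) are skipped.
    Reproducible: the same inputs and seed give a bit-identical interval.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise UndefinedCorrelationError(f"need ≥ 3 complete pairs, got {n}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    xs, ys = x[idx], y[idx]
    xc = xs - xs.mean(axis=1, keepdims=True)
    yc = ys - ys.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc * xc).sum(axis=1) * (yc * yc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc).sum(axis=1) / denom
    r = r[np.isfinite(r)]  # degenerate resamples dropped
    if r.size == 0:
        raise UndefinedCorrelationError("all bootstrap resamples degenerate")
    lo_q, hi_q = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
    lo, hi = np.quantile(r, [lo_q, hi_q])
    return float(np.clip(lo, -1, 1)), float(np.clip(hi, -1, 1))


def interpret_r(r: float) -> str:
    """Effect-size band of |r|: trivial < 0.1 ≤ small < 0.3 ≤ moderate < 0.5 ≤
    large < 0.7 ≤ very large < 0.9 ≤ nearly perfect ≤ 1.

    Bands are half-open on the left so shared endpoints resolve upward
    (|r| = 0.5 is "large").
    """
    a = abs(r)
    if a > 1.0:
        raise InvalidParameterError(f"|r| must not exceed 1, got {r}")
    for lo, hi, label in EFFECT_BANDS:
        if lo <= a < hi:
            return label
    return "nearly perfect"  # a == 1.0


# ---------------------------------------------------------------------------
# Power: minimum detectable correlation
# ---------------------------------------------------------------------------

def _r_critical(n: int, alpha: float) -> float:
    t = sstats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return t / math.sqrt(t * t + n - 2)


def _sample_r_pdf(r: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Exact density of the sample correlation under a bivariate normal."""
    log_c = (math.log(n - 2) + special.gammaln(n - 1)
             - 0.5 * math.log(2 * math.pi) - special.gammaln(n - 0.5))
    val = (np.exp(log_c)
           * (1.0 - rho * rho) ** ((n - 1) / 2.0)
           * (1.0 - r * r) ** ((n - 4) / 2.0)
           * (1.0 - rho * r) ** (-(n - 1.5)))
    return val * special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1.0) / 2.0)


def pearson_power(rho: float, n: int, alpha: float = 0.05) -> float:
    """Exact power of the two-tailed Pearson test at population correlation ρ."""
    if n <= 3:
        raise InvalidParameterError("need n > 3")
    rc = _r_critical(n, alpha)
    # the density peaks near rho; tell the integrator where to look
    up_pts = [rho] if rc < rho < 1.0 else None
    lo_pts = [rho] if -1.0 < rho < -rc else None
    upper, _ = integrate.quad(_sample_r_pdf, rc, 1.0, args=(rho, n),
                              points=up_pts, limit=200)
    lower, _ = integrate.quad(_sample_r_pdf, -1.0, -rc, args=(rho, n),
                              points=lo_pts, limit=200)
    return float(upper + lower)


def min_detectable_r(n: int, alpha: float = 0.05, power: float = 0.80) -> float:
    """Smallest |ρ| reliably detected by a two-tailed Pearson test.

    A Fisher-z start brackets the root; the exact sample-correlation
    distribution then pins down the value, matching the sensitivity analyses
    of standard power software.  Round to 2 decimals for reporting.
    """
    spec = PowerSpec(n=n, alpha=alpha, power=power)  # validates inputs
    # Fisher-z initial guess
    za = sstats.norm.ppf(1.0 - alpha / 2.0)
    zb = sstats.norm.ppf(power)
    guess = math.tanh((za + zb) / math.sqrt(n - 3))
    # the exact density is numerically fragile above |rho| ~ 0.999; treat that
    # as the attainability boundary
    r_max = 0.999
    lo = max(1e-6, min(guess, r_max) - 0.2)
    hi = min(r_max, guess + 0.2)

    def f(rho: float) -> float:
        return pearson_power(rho, spec.n, spec.alpha) - spec.power

    while f(lo) > 0 and lo > 1e-6:
        lo = max(1e-6, lo - 0.2)
    while f(hi) < 0:
        if hi >= r_max:
            raise InvalidParameterError("target power unattainable at this n")
        hi = min(r_max, hi + 0.1)
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def monte_carlo_power(rho: float, n: int, alpha: float = 0.05,
                      n_sim: int = 20000, seed: int = 0) -> float:
    """Simulated rejection rate of the two-tailed Pearson test at ρ."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_sim, n, 2))
    x = z[:, :, 0]
    y = rho * z[:, :, 0] + math.sqrt(1.0 - rho * rho) * z[:, :, 1]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    r = (xc * yc).sum(axis=1) / np.sqrt((xc * xc).sum(axis=1) * (yc * yc).sum(axis=1))
    return float(np.mean(np.abs(r) > _r_critical(n, alpha)))


# ---------------------------------------------------------------------------
# The correlation study
# ---------------------------------------------------------------------------

def default_design(speeds: tuple[int, ...] = SPEEDS,
                   y_kind: str = "cna") -> tuple[FamilySpec, ...]:
    """The joint-matched study design.

    Family ``isokinetic_cna``: knee strength variables against knee-muscle
    activation and ankle strength against ankle-muscle activation, at every
    speed.  Family ``imtp_cna``: IMTP relative PF and the five RFD windows
    against every muscle at every speed.
    """
    col = {"cna": cna_column, "iemg": iemg_column}[y_kind]
    iso_pairs = []
    for speed in speeds:
        for x in ("Kflex_con", "Kex_con", "Kflex_ecc", "Kex_ecc"):
            iso_pairs += [(x, col(m, speed), float(speed)) for m in KNEE_MUSCLES]
        for x in ("Adors_con", "Aplan_con", "Adors_ecc", "Aplan_ecc"):
            iso_pairs += [(x, col(m, speed), float(speed)) for m in ANKLE_MUSCLES]
    imtp_pairs = [
        (x, col(m, speed), float(speed))
        for speed in speeds for x in IMTP_VARS for m in MUSCLES
    ]
    return (
        FamilySpec(f"isokinetic_{y_kind}", tuple(iso_pairs)),
        FamilySpec(f"imtp_{y_kind}", tuple(imtp_pairs)),
    )


def correlation_study(table: pd.DataFrame, design: tuple[FamilySpec, ...],
                      alpha: float = 0.05, bootstrap_B: int = 1999,
                      seed: int = 0) -> pd.DataFrame:
    """Run every declared pair: Pearson r, BH-adjusted p within each family,
    bootstrap CI, effect-size band and significance flag.

    Self-pairs (x == y) are rejected; bootstrap CIs are skipped when
    ``bootstrap_B`` is 0 (NaN bounds).  Deterministic given ``seed``.
    """
    missing = sorted(
        {c for fam in design for pair in fam.pairs for c in pair[:2]}
        - set(table.columns)
    )
    if missing:
        raise ConfigError(f"cohort table is missing columns: {missing}")

    rows = []
    n_pairs = sum(len(fam.pairs) for fam in design)
    seeds = iter(np.random.SeedSequence(seed).spawn(max(n_pairs, 1)))
    for fam in design:
        fam_rows = []
        for x_name, y_name, speed in fam.pairs:
            if x_name == y_name:
                raise ConfigError(f"self-pair {x_name!r} excluded by design")
            pair_seed = next(seeds)
            r, p_raw, n_used = pearson_with_p(table[x_name], table[y_name])
            if bootstrap_B > 0:
                lo, hi = bootstrap_ci(table[x_name].to_numpy(),
                                      table[y_name].to_numpy(),
                                      B=bootstrap_B,
                                      seed=pair_seed.generate_state(1)[0])
            else:
                lo, hi = float("nan"), float("nan")
            fam_rows.append({
                "family": fam.family_id, "x": x_name, "y": y_name,
                "speed": speed, "n": n_used, "r": r, "p_raw": p_raw,
                "ci_lo": lo, "ci_hi": hi, "band": interpret_r(r),
            })
        p_adj = bh_adjust(np.array([row["p_raw"] for row in fam_rows]))
        for row, pa in zip(fam_rows, p_adj):
            row["p_adj"] = float(pa)
            row["significant"] = bool(pa < alpha)
        rows.extend(fam_rows)
    columns = ["family", "x", "y", "speed", "n", "r", "p_raw", "p_adj",
               "ci_lo", "ci_hi", "band", "significant"]
    return pd.DataFrame(rows, columns=columns)


def heatmap_matrices(results: pd.DataFrame) -> dict[tuple[str, float], pd.DataFrame]:
    """Numeric heatmap exports: one r matrix (strength var × muscle column)
    per family and speed."""
    out: dict[tuple[str, float], pd.DataFrame] = {}
    for (family, speed), grp in results.groupby(["family", "speed"], sort=True):
        out[(family, float(speed))] = grp.pivot(index="x", columns="y", values="r")
    return out


def sensitivity_variants(table: pd.DataFrame, design: tuple[FamilySpec, ...],
                         alpha: float = 0.05, bootstrap_B: int = 0,
                         seed: int = 0) -> dict[str, pd.DataFrame]:
    """Re-run the study with (a) per-cycle iEMG outcomes and (b) fat-free-mass
    normalised strength, and summarise sign agreement with the main analysis.

    Variant columns that are absent from the table are skipped with a warning
    rather than raised, so partial datasets still produce the main analysis.
    Returns a dict with keys ``main``, ``per_cycle_iemg``, ``ffm_normalized``
    (when computable) and ``sign_agreement``.
    """
    out: dict[str, pd.DataFrame] = {}
    main = correlation_study(table, design, alpha=alpha, bootstrap_B=bootstrap_B,
                             seed=seed)
    out["main"] = main

    def _swap_y(pairs):
        return tuple(
            (x, y.replace("_cna_", "_iemg_"), s) for x, y, s in pairs
        )

    iemg_design = tuple(
        FamilySpec(fam.family_id + "__iemg", _swap_y(fam.pairs)) for fam in design
    )
    iemg_cols = {c for fam in iemg_design for pair in fam.pairs for c in pair[1:2]}
    if iemg_cols <= set(table.columns):
        out["per_cycle_iemg"] = correlation_study(
            table, iemg_design, alpha=alpha, bootstrap_B=bootstrap_B, seed=seed
        )
    else:
        warnings.warn("per-cycle iEMG columns missing; skipping that variant",
                      stacklevel=2)

    if {"body_mass_kg", "ffm_kg"} <= set(table.columns):
        ffm_table = table.copy()
        x_cols = sorted({x for fam in design for x, _, _ in fam.pairs})
        ratio = ffm_table["body_mass_kg"] / ffm_table["ffm_kg"]
        for x in x_cols:
            ffm_table[x + "_ffm"] = ffm_table[x] * ratio
        ffm_design = tuple(
            FamilySpec(fam.family_id + "__ffm",
                       tuple((x + "_ffm", y, s) for x, y, s in fam.pairs))
            for fam in design
        )
        out["ffm_normalized"] = correlation_study(
            ffm_table, ffm_design, alpha=alpha, bootstrap_B=bootstrap_B, seed=seed
        )
    else:
        warnings.warn("body_mass_kg/ffm_kg columns missing; skipping FFM variant",
                      stacklevel=2)

    agreements = []
    for name, variant in out.items():
        if name == "main":
            continue
        v = variant.copy()
        v["y_base"] = v["y"].str.replace("_iemg_", "_cna_", regex=False)
        v["x_base"] = v["x"].str.replace("_ffm", "", regex=False)
        merged = main.merge(v, left_on=["x", "y", "speed"],
                            right_on=["x_base", "y_base", "speed"],
                            suffixes=("_main", "_variant"))
        frac = float(np.mean(np.sign(merged["r_main"]) == np.sign(merged["r_variant"])))
        agreements.append({"variant": name, "n_pairs": len(merged),
                           "sign_agreement": frac})
    out["sign_agreement"] = pd.DataFrame(
        agreements, columns=["variant", "n_pairs", "sign_agreement"]
    )
    return out
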