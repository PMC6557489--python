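"""From raw reporter tables to fold-changes, CRM classes, and qPCR ratios.

Construct activity is the robust EIV slope of Firefly vs Renilla
luminescence for the replicate wells of one (construct, condition) group.
Fold-change is a ratio of slopes, either against the promoter-only
construct in the *uninduced* condition (one shared baseline across
conditions) or against the promoter-only construct in the *same* condition
(per-condition normalization).  Confidence intervals on folds pair the
bootstrap slope replicates of numerator and denominator by replicate index
and apply the basic bootstrap to the ratio.

qPCR threshold cycles are converted to relative expression with the ΔCt
convention, 2^(−(Ct_target − Ct_reference)), normalized to the mean of the
uninduced samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .eiv_normalization import (
    RobustConfig,
    SlopeFit,
    bootstrap_slope_replicates,
    eiv_slope,
)

logger = logging.getLogger(__name__)

PROMOTER_ONLY = "0"
UNINDUCED = "uninduced"

MODE_VS_UNINDUCED_PROMOTER = "vs_uninduced_promoter"
MODE_VS_SAME_CONDITION_PROMOTER = "vs_same_condition_promoter"


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class TableDialect:
    """Column names and condition mapping for a luminescence CSV.

    The default matches the dual-reporter table layout with Luc/Ren
    luminescence columns, a Construct column ("0" = promoter alone), an OHT
    true/false column, an optional Cytokine column, and a free-text note.
    Conditions are canonicalized by ``condition_map`` keyed on
    (oht, cytokine); a preexisting Condition column wins if present.
    """

    firefly: str = "Luc"
    renilla: str = "Ren"
    construct: str = "Construct"
    oht: str = "OHT"
    cytokine: str = "Cytokine"
    note: str = "note"
    condition: str = "Condition"
    condition_map: tuple = (
        ((False, "IL3"), UNINDUCED),
        ((False, "GCSF"), UNINDUCED),
        ((False, None), UNINDUCED),
        ((True, "IL3"), "IL3+OHT"),
        ((True, "GCSF"), "GCSF+OHT"),
        ((None, None), "G1ME"),
    )


def load_luminescence_table(path, dialect: TableDialect = TableDialect()) -> pd.DataFrame:
    """Read and type a luminescence CSV; rows with non-finite luminescence
    are dropped (count logged)."""
    df = pd.read_csv(path)
    for col in (dialect.firefly, dialect.renilla, dialect.construct):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    out = pd.DataFrame(
        {
            "firefly": pd.to_numeric(df[dialect.firefly], errors="coerce"),
            "renilla": pd.to_numeric(df[dialect.renilla], errors="coerce"),
            "construct": df[dialect.construct].astype(str),
        }
    )
    if out["construct"].str.len().eq(0).any():
        raise SchemaError(f"{path}: empty construct ids")
    if dialect.condition in df.columns:
        out["condition"] = df[dialect.condition].astype(str)
    else:
        cmap = dict(dialect.condition_map)
        oht = (
            df[dialect.oht].map(_to_bool)
            if dialect.oht in df.columns
            else pd.Series([None] * len(df))
        )
        cyt = (
            df[dialect.cytokine].astype(str).str.upper()
            if dialect.cytokine in df.columns
            else pd.Series([None] * len(df))
        )
        conditions = []
        for o, c in zip(oht, cyt):
            key = (o, c) if (o, c) in cmap else (o, None)
            if key not in cmap:
                key = (None, None)
            conditions.append(cmap[key])
        out["condition"] = conditions
    out["note"] = df[dialect.note] if dialect.note in df.columns else "wildtype"
    keep = np.isfinite(out["firefly"]) & np.isfinite(out["renilla"])
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d rows with non-finite luminescence", dropped)
    return out[keep].reset_index(drop=True)


def _to_bool(v):
    if isinstance(v, str):
        return v.strip().lower() in ("true", "t", "1", "yes")
    return bool(v)


@dataclass(frozen=True)
class FoldChange:
    construct: str
    condition: str
    mode: str
    value: float
    ci: Optional[tuple[float, float]] = None


def group_slope(
    table: pd.DataFrame,
    construct: str,
    condition: str,
    config: RobustConfig = RobustConfig(),
) -> SlopeFit:
    """Robust EIV slope for one (construct, condition) group."""
    g = table[(table["construct"] == construct) & (table["condition"] == condition)]
    if len(g) < 3:
        raise ValueError(
            f"group ({construct!r}, {condition!r}) has {len(g)} rows; >= 3 required"
        )
    return eiv_slope(g["renilla"].to_numpy(), g["firefly"].to_numpy(), config)


def fold_change(
    table: pd.DataFrame,
    construct: str,
    condition: str,
    mode: str = MODE_VS_UNINDUCED_PROMOTER,
    config: RobustConfig = RobustConfig(),
    seed: Optional[int] = None,
) -> FoldChange:
    """Ratio of construct slope to the promoter-only reference slope.

    The reference group is promoter-only in the uninduced condition
    (``vs_uninduced_promoter``) or in the same condition
    (``vs_same_condition_promoter``).  With a seed, a basic-bootstrap CI is
    computed from index-paired replicate slopes of the two groups.
    """
    if mode == MODE_VS_UNINDUCED_PROMOTER:
        ref_condition = (
            UNINDUCED if UNINDUCED in set(table["condition"]) else condition
        )
    elif mode == MODE_VS_SAME_CONDITION_PROMOTER:
        ref_condition = condition
    else:
        raise ValueError(f"unknown mode {mode!r}")
    num = table[(table["construct"] == construct) & (table["condition"] == condition)]
    den = table[
        (table["construct"] == PROMOTER_ONLY) & (table["condition"] == ref_condition)
    ]
    if len(den) == 0:
        raise ValueError(
            f"missing promoter-only reference group for condition {ref_condition!r}"
        )
    if len(num) < 3 or len(den) < 3:
        raise ValueError("both groups need >= 3 rows")
    if seed is None:
        b_num = eiv_slope(num["renilla"].to_numpy(), num["firefly"].to_numpy(), config).beta
        b_den = eiv_slope(den["renilla"].to_numpy(), den["firefly"].to_numpy(), config).beta
        return FoldChange(construct, condition, mode, b_num / b_den, None)
    ss = np.random.SeedSequence(seed).spawn(2)
    seed_num, seed_den = (int(s.generate_state(1)[0] % (2**31)) for s in ss)
    b_num, reps_num = bootstrap_slope_replicates(
        num["renilla"].to_numpy(), num["firefly"].to_numpy(), config, seed_num
    )
    b_den, reps_den = bootstrap_slope_replicates(
        den["renilla"].to_numpy(), den["firefly"].to_numpy(), config, seed_den
    )
    value = b_num / b_den
    m = min(reps_num.size, reps_den.size)
    ratios = reps_num[:m] / reps_den[:m]
    alpha = 1.0 - config.ci_level
    q_lo, q_hi = np.quantile(ratios, [alpha / 2.0, 1.0 - alpha / 2.0])
    ci = (float(2.0 * value - q_hi), float(2.0 * value - q_lo))
    return FoldChange(construct, condition, mode, float(value), ci)


ENHANCER = "enhancer"
SILENCER = "silencer"
NEUTRAL = "neutral"


@dataclass(frozen=True)
class CRMClass:
    construct: str
    label: str
    conflicting_conditions: tuple[str, ...] = ()


def classify_crm(folds: Sequence[FoldChange]) -> list[CRMClass]:
    """Classify each construct from its fold-change CIs.

    Enhancer if the CI excludes 1 from above in any condition; silencer if
    it excludes 1 from below in some condition and is never an enhancer;
    otherwise neutral.  Constructs showing both behaviors are classified as
    enhancers with the silencing conditions reported as conflicts.
    """
    out = []
    for construct in sorted({f.construct for f in folds}):
        ups, downs = [], []
        for f in folds:
            if f.construct != construct:
                continue
            if f.ci is None:
                raise ValueError(f"fold for {construct} lacks a CI")
            if f.ci[0] > 1.0:
                ups.append(f.condition)
            elif f.ci[1] < 1.0:
                downs.append(f.condition)
        if ups:
            out.append(
                CRMClass(construct, ENHANCER, tuple(downs) if downs else ())
            )
        elif downs:
            out.append(CRMClass(construct, SILENCER))
        else:
            out.append(CRMClass(construct, NEUTRAL))
    return out


# ---------------------------------------------------------------------------
# qPCR


def qpcr_relative_expression(
    records: pd.DataFrame,
    ct_target: str = "Ct_target",
    ct_reference: str = "Ct_reference",
    uninduced: str = "uninduced_flag",
) -> pd.DataFrame:
    """Relative expression 2^(−ΔCt), normalized to the uninduced mean.

    ``records`` needs the two Ct columns plus a boolean column marking
    uninduced samples.  Returns the table with ``raw`` (2^(−ΔCt)) and
    ``relative_expression`` (raw / mean raw over uninduced samples).
    """
    for col in (ct_target, ct_reference, uninduced):
        if col not in records.columns:
            raise SchemaError(f"missing column {col!r}")
    ct_t = records[ct_target].to_numpy(dtype=float)
    ct_r = records[ct_reference].to_numpy(dtype=float)
    if ((ct_t <= 0) | (ct_t >= 45) | (ct_r <= 0) | (ct_r >= 45)).any():
        raise ValueError("threshold cycles must lie in (0, 45)")
    raw = 2.0 ** (-(ct_t - ct_r))
    mask = records[uninduced].astype(bool).to_numpy()
    if not mask.any():
        raise ValueError("no uninduced replicates to normalize against")
    out = records.copy()
    out["raw"] = raw
    out["relative_expression"] = raw / raw[mask].mean()
    return out


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon rank-sum test (two-sided).

    Exact null distribution when the pooled sample has no ties and n ≤ 20;
    mid-rank/normal approximation with continuity correction otherwise.
    Returns (W, p) with W the rank-sum statistic of sample ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([a, b])
    exact = pooled.size <= 20 and np.unique(pooled).size == pooled.size
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic",
        use_continuity=not exact,
    )
    w = float(res.statistic + a.size * (a.size + 1) / 2.0)  # U -> rank sum
    return w, float(res.pvalue)


def fold_change_table(
    table: pd.DataFrame,
    mode: str = MODE_VS_UNINDUCED_PROMOTER,
    config: RobustConfig = RobustConfig(),
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Fold-changes for every (construct, condition) group in the table."""
    rows = []
    for (construct, condition), _ in table.groupby(["construct", "condition"]):
        fc = fold_change(table, construct, condition, mode, config, seed)
        rows.append(
            {
                "construct": construct,
                "condition": condition,
                "fold": fc.value,
                "ci_low": fc.ci[0] if fc.ci else np.nan,
                "ci_high": fc.ci[1] if fc.ci else np.nan,
            }
        )
    return pd.DataFrame(rows)
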