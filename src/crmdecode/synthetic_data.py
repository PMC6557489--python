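"""Synthetic data generators with carried ground truth.

Every generator is a pure function of its arguments, including the seed,
and returns a ``SyntheticTruth`` sidecar sufficient to re-run recovery
tests.  The generators emulate the statistical structure the analysis
assumes in real dual-luciferase experiments:

* luminescence wells share a latent multiplicative transfection efficiency
  (log-normal; default sdlog 0.35 reproduces the observed 2–4 fold
  sample-to-sample span at n = 10) with independent multiplicative
  measurement noise per channel and occasional gross Firefly outliers;
* CRM sequences are i.i.d.-background DNA with planted motif-consensus
  sites recoverable at relative affinity q = 1;
* reporter fold tables are model-truth folds under log-normal noise,
  optionally expanded to raw luminescence wells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .sequence_sites import (
    AlignmentMatrix,
    BASES,
    CRMRecord,
    reverse_complement,
)
from .thermo_model import ThermoModelSpec, predict_mutant_series

DEFAULT_N_REPLICATES = 10
DEFAULT_TRANSFECTION_SDLOG = 0.35


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth carried alongside generated data."""

    seed: int
    true_slope: Optional[dict] = None  # group key -> beta
    true_fold: Optional[dict] = None  # (construct, condition) -> fold
    planted_sites: Optional[tuple] = None  # (tf_name, start, strand)
    outlier_rows: Optional[tuple] = None
    params: dict = field(default_factory=dict)


def simulate_luminescence(
    true_beta: float,
    n: int = DEFAULT_N_REPLICATES,
    transfection_sdlog: float = DEFAULT_TRANSFECTION_SDLOG,
    measurement_cv: float = 0.1,
    outlier_frac: float = 0.0,
    outlier_scale: float = 10.0,
    seed: int = 0,
    construct: str = "0",
    condition: str = "uninduced",
    renilla_scale: float = 1.0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Paired Firefly/Renilla wells with shared transfection efficiency.

    Renilla_i = T_i·(1 + ε_i), Firefly_i = β·T_i·(1 + δ_i) with
    T_i ~ lognormal(0, sdlog) and ε, δ mean-zero with sd = measurement_cv.
    A fraction of wells get their Firefly reading multiplied by
    ``outlier_scale`` (gross contamination / pipetting errors).
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    if not (0 <= outlier_frac <= 1):
        raise ValueError("outlier_frac must be in [0,1]")
    rng = np.random.default_rng(seed)
    t = rng.lognormal(mean=0.0, sigma=transfection_sdlog, size=n) * renilla_scale
    eps = rng.normal(0.0, measurement_cv, size=n)
    dlt = rng.normal(0.0, measurement_cv, size=n)
    renilla = t * (1.0 + eps)
    firefly = true_beta * t * (1.0 + dlt)
    n_out = int(round(outlier_frac * n))
    out_rows: tuple[int, ...] = ()
    if n_out > 0:
        out_rows = tuple(sorted(rng.choice(n, size=n_out, replace=False).tolist()))
        firefly[list(out_rows)] *= outlier_scale
    table = pd.DataFrame(
        {
            "firefly": firefly,
            "renilla": renilla,
            "construct": construct,
            "condition": condition,
            "note": "synthetic",
        }
    )
    truth = SyntheticTruth(
        seed=seed,
        true_slope={(construct, condition): true_beta},
        outlier_rows=out_rows,
        params={
            "n": n,
            "transfection_sdlog": transfection_sdlog,
            "measurement_cv": measurement_cv,
            "outlier_frac": outlier_frac,
            "outlier_scale": outlier_scale,
        },
    )
    return table, truth


def simulate_crm(
    length: int,
    planted: Sequence[tuple[AlignmentMatrix, int, str]] = (),
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    crm_id: str = "synthetic_crm",
    role: str = "distal_crm",
) -> tuple[CRMRecord, SyntheticTruth]:
    """Background DNA with matrix-consensus sites planted at given positions.

    Planted sites must be non-overlapping and within bounds; minus-strand
    plants insert the reverse complement of the consensus so a both-strand
    scan recovers them with q = 1.
    """
    intervals = []
    for mat, pos, strand in planted:
        if strand not in "+-":
            raise ValueError("strand must be + or -")
        if pos < 0 or pos + len(mat) > length:
            raise ValueError(f"planted site at {pos} outside sequence bounds")
        intervals.append((pos, pos + len(mat)))
    intervals.sort()
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise ValueError("planted sites overlap")
    rng = np.random.default_rng(seed)
    bg = np.asarray(background, dtype=float)
    bg = bg / bg.sum()
    seq = list("".join(rng.choice(list(BASES), size=length, p=bg)))
    truth_sites = []
    for mat, pos, strand in planted:
        site = mat.consensus if strand == "+" else reverse_complement(mat.consensus)
        seq[pos : pos + len(mat)] = site
        truth_sites.append((mat.tf_name, pos, strand))
    crm = CRMRecord(id=crm_id, sequence="".join(seq), role=role)
    truth = SyntheticTruth(
        seed=seed,
        planted_sites=tuple(truth_sites),
        params={"length": length, "background": tuple(bg)},
    )
    return crm, truth


def simulate_reporter_dataset(
    constructs: Sequence[tuple[str, CRMRecord, Optional[CRMRecord]]],
    spec: ThermoModelSpec,
    matrices: Sequence[AlignmentMatrix],
    conditions: Sequence[str],
    noise_cv: float = 0.0,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int = 0,
    expand_luminescence: bool = False,
    promoter_slope: float = 1.0,
    **luminescence_kwargs,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Reporter folds drawn from model truth under log-normal noise.

    Returns a fold table (construct, condition, fold) — or, when
    ``expand_luminescence`` is set, a raw luminescence table where each
    group's true slope is fold × ``promoter_slope``.
    """
    truth_df = predict_mutant_series(constructs, spec, matrices, conditions)
    rng = np.random.default_rng(seed)
    sdlog = np.sqrt(np.log1p(noise_cv**2))
    true_fold = {
        (r.construct, r.condition): r.fold for r in truth_df.itertuples()
    }
    if not expand_luminescence:
        noisy = truth_df.copy()
        noisy["fold"] = truth_df["fold"].to_numpy() * rng.lognormal(
            -0.5 * sdlog**2, sdlog, size=len(truth_df)
        )
        truth = SyntheticTruth(
            seed=seed,
            true_fold=true_fold,
            params={"noise_cv": noise_cv, "n_replicates": n_replicates},
        )
        return noisy[["construct", "condition", "fold"]], truth
    tables = []
    true_slopes = {}
    child_seeds = np.random.SeedSequence(seed).spawn(len(truth_df))
    for row, ss in zip(truth_df.itertuples(), child_seeds):
        beta = row.fold * promoter_slope
        true_slopes[(row.construct, row.condition)] = beta
        tab, _ = simulate_luminescence(
            true_beta=beta,
            n=n_replicates,
            measurement_cv=noise_cv,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            construct=row.construct,
            condition=row.condition,
            **luminescence_kwargs,
        )
        tables.append(tab)
    truth = SyntheticTruth(
        seed=seed,
        true_fold=true_fold,
        true_slope=true_slopes,
        params={"noise_cv": noise_cv, "n_replicates": n_replicates},
    )
    return pd.concat(tables, ignore_index=True), truth


def simulate_fold_table(
    true_folds: dict,
    n_replicates: int = DEFAULT_N_REPLICATES,
    transfection_sdlog: float = DEFAULT_TRANSFECTION_SDLOG,
    measurement_cv: float = 0.1,
    outlier_frac: float = 0.0,
    outlier_scale: float = 10.0,
    promoter_slope: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Raw luminescence wells for an arbitrary {(construct, condition): fold}
    truth table (fold = 1 groups are generated too; the promoter-only
    reference group must be included by the caller)."""
    child = np.random.SeedSequence(seed).spawn(len(true_folds))
    tables, slopes = [], {}
    for ((construct, condition), fold), ss in zip(sorted(true_folds.items()), child):
        beta = fold * promoter_slope
        slopes[(construct, condition)] = beta
        tab, _ = simulate_luminescence(
            true_beta=beta,
            n=n_replicates,
            transfection_sdlog=transfection_sdlog,
            measurement_cv=measurement_cv,
            outlier_frac=outlier_frac,
            outlier_scale=outlier_scale,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            construct=construct,
            condition=condition,
        )
        tables.append(tab)
    truth = SyntheticTruth(
        seed=seed,
        true_fold=dict(true_folds),
        true_slope=slopes,
        params={
            "n_replicates": n_replicates,
            "transfection_sdlog": transfection_sdlog,
            "measurement_cv": measurement_cv,
            "outlier_frac": outlier_frac,
            "outlier_scale": outlier_scale,
        },
    )
    return pd.concat(tables, ignore_index=True), truth


def simulate_qpcr(
    n_per_group: int = 13,
    il3_delta_ct: float = 5.0,
    gcsf_shift_cycles: float = 1.0,
    noise_sd_cycles: float = 0.25,
    ct_reference: float = 20.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Threshold-cycle table for two pooled cytokine groups.

    GCSF samples run ``gcsf_shift_cycles`` cycles earlier on the target than
    IL3 samples, i.e. a 2^shift expression ratio (default 2-fold).  A set of
    uninduced samples (the IL3 baseline) anchors the normalization.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cytokine, shift in (("IL3", 0.0), ("GCSF", gcsf_shift_cycles)):
        for i in range(n_per_group):
            rows.append(
                {
                    "time_h": 24 * (1 + i % 4),
                    "replicate": i,
                    "cytokine": cytokine,
                    "oht": True,
                    "Ct_target": ct_reference
                    + il3_delta_ct
                    - shift
                    + rng.normal(0, noise_sd_cycles),
                    "Ct_reference": ct_reference + rng.normal(0, noise_sd_cycles),
                }
            )
    for i in range(max(3, n_per_group // 3)):
        rows.append(
            {
                "time_h": 0,
                "replicate": i,
                "cytokine": "IL3",
                "oht": False,
                "Ct_target": ct_reference + il3_delta_ct + rng.normal(0, noise_sd_cycles),
                "Ct_reference": ct_reference + rng.normal(0, noise_sd_cycles),
            }
        )
    df = pd.DataFrame(rows)
    df["uninduced_flag"] = ~df["oht"]
    truth = SyntheticTruth(
        seed=seed,
        params={
            "true_ratio_gcsf_vs_il3": 2.0**gcsf_shift_cycles,
            "n_per_group": n_per_group,
            "noise_sd_cycles": noise_sd_cycles,
        },
    )
    return df, truth


# ---------------------------------------------------------------------------
# Reference activity pattern for end-to-end validation
#
# Fold-changes (construct activity / promoter-only activity) emulating the
# measured behavior of the Cebpa CRM reporter panel: four enhancers with
# condition-specific activity, their site-ablated mutants, the shorter +37kb
# enhancer core whose flanking sequence is repressive, and three silencers
# active only in the erythroid (G1ME) background.  Used as ground truth by
# the synthetic luminescence generator so the normalize -> fold-change chain
# can be validated end to end without measurement data.

REFERENCE_ENHANCER_FOLDS = {
    ("0", "uninduced"): 1.0,
    ("0", "IL3+OHT"): 1.0,
    ("0", "GCSF+OHT"): 1.0,
    ("7", "uninduced"): 6.0,
    ("7", "IL3+OHT"): 3.0,
    ("7", "GCSF+OHT"): 4.5,
    ("14", "uninduced"): 2.5,
    ("16", "uninduced"): 2.0,
    ("16", "GCSF+OHT"): 4.1,
    ("18", "uninduced"): 1.5,
    ("18", "GCSF+OHT"): 2.5,
    # mutants (uninduced unless noted): C/EBP-site mutant of CRM7 loses
    # ~40% of activity; the C/EBP+Gfi1 mutant falls 3-fold below wildtype;
    # the Egr1 mutant of CRM14 loses ~35%; the PU.1 mutant of CRM16 loses
    # ~43% in GCSF
    ("7m1", "uninduced"): 6.0 * 0.60,
    ("7m2", "uninduced"): 2.0,
    ("14m1", "uninduced"): 2.5 * 0.65,
    ("16m1", "GCSF+OHT"): 4.1 * 0.57,
    # +37kb enhancer core is ~2.5x the full-length CRM18 construct
    ("37kb", "uninduced"): 1.5 * 2.5,
}

REFERENCE_SILENCER_FOLDS = {
    ("0", "G1ME"): 1.0,
    ("9", "G1ME"): 1.0 / 3.0,
    ("11", "G1ME"): 1.0 / 3.0,
    ("24", "G1ME"): 1.0 / 3.0,
}
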