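"""Thermodynamic model of CRM-driven transcription.

Given annotated binding sites, TF roles (activator/repressor), and
per-condition TF concentrations, the model

1. computes fractional site occupancies from a Boltzmann-weighted ensemble
   over all configurations of non-overlapping bound sites (statistical
   weight of a bound site: K·q·ν, with optional cooperativity factors ω
   between declared adjacent partners);
2. quenches activator occupancies near bound repressors: each repressor
   site j within the quenching range d_q (edge-to-edge, default 150 bp)
   multiplies an activator's occupancy by (1 − γ_j·O_j);
3. sums effective activator occupancies weighted by activation
   efficiencies α into the interaction strength E with the basal machinery;
4. applies long-range (dominant) repression, E′ = E·Π_j(1 − β_R,j·O_j)
   over all repressor sites — this is what lets distal silencers push
   activity below the promoter-alone baseline;
5. converts interaction strength to a transcription rate by an enzymatic
   barrier law, r = R_max·exp(−max(0, θ − E′)).

Occupancies are computed by dynamic programming over sites sorted by start
position; ``enumerate_configurations`` is the brute-force oracle kept for
verification on small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .sequence_sites import (
    AlignmentMatrix,
    BindingSite,
    CRMRecord,
    DEFAULT_Q_MIN,
    scan_sites,
)

DEFAULT_QUENCH_RANGE = 150  # bp, edge-to-edge
DEFAULT_COOP_GAP = 50  # bp
DEFAULT_SPACER_BP = 2000  # site-free vector backbone stand-in

MAX_ENUM_SITES = 22


class ValidationError(ValueError):
    pass


class OracleSizeError(ValueError):
    """Brute-force enumeration requested on too many sites."""


@dataclass(frozen=True)
class Cooperativity:
    partner: str
    omega: float
    max_gap: int = DEFAULT_COOP_GAP

    def __post_init__(self):
        if self.omega < 0:
            raise ValidationError("cooperativity omega must be >= 0")


@dataclass(frozen=True)
class TFSpec:
    """Role and thermodynamic parameters for one TF.

    ``binding_scale`` K sets the statistical weight K·q·ν of a bound site.
    Activators carry an activation efficiency α; repressors carry a
    quenching efficiency γ ∈ [0,1] acting within ``quench_range`` bp and a
    long-range efficiency β_R ∈ [0,1].
    """

    name: str
    role: str  # 'activator' | 'repressor'
    binding_scale: float = 1.0
    activation_efficiency: Optional[float] = None
    quenching_efficiency: Optional[float] = None
    quench_range: int = DEFAULT_QUENCH_RANGE
    longrange_efficiency: Optional[float] = None
    cooperativity: Optional[Cooperativity] = None

    def __post_init__(self):
        if self.role not in ("activator", "repressor"):
            raise ValidationError(f"{self.name}: role must be activator|repressor")
        if self.binding_scale <= 0:
            raise ValidationError(f"{self.name}: binding_scale must be > 0")
        if self.role == "activator":
            if self.activation_efficiency is None:
                object.__setattr__(self, "activation_efficiency", 1.0)
            if self.activation_efficiency < 0:
                raise ValidationError(f"{self.name}: negative activation efficiency")
            if (
                self.quenching_efficiency is not None
                or self.longrange_efficiency is not None
            ):
                raise ValidationError(
                    f"{self.name}: repressor fields set on an activator"
                )
        else:
            if self.activation_efficiency is not None:
                raise ValidationError(
                    f"{self.name}: activator fields set on a repressor"
                )
            if self.quenching_efficiency is None:
                object.__setattr__(self, "quenching_efficiency", 1.0)
            if self.longrange_efficiency is None:
                object.__setattr__(self, "longrange_efficiency", 0.0)
            if not (0 <= self.quenching_efficiency <= 1):
                raise ValidationError(f"{self.name}: quenching efficiency not in [0,1]")
            if not (0 <= self.longrange_efficiency <= 1):
                raise ValidationError(f"{self.name}: long-range efficiency not in [0,1]")


@dataclass(frozen=True)
class ThermoModelSpec:
    """Full model: TF table, barrier θ, maximal rate, named conditions."""

    tfs: tuple[TFSpec, ...]
    theta: float
    r_max: float = 1.0
    conditions: dict = field(default_factory=dict)  # name -> {tf: concentration}

    def __post_init__(self):
        if self.theta <= 0:
            raise ValidationError("barrier theta must be > 0")
        if self.r_max <= 0:
            raise ValidationError("r_max must be > 0")
        names = [tf.name for tf in self.tfs]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate TF names in model spec")
        object.__setattr__(self, "tfs", tuple(self.tfs))

    def tf(self, name: str) -> TFSpec:
        for t in self.tfs:
            if t.name == name:
                return t
        raise ValidationError(f"TF {name!r} not in model spec")

    def concentrations(self, condition: str) -> dict:
        if condition not in self.conditions:
            raise ValidationError(
                f"no concentration vector for condition {condition!r}"
            )
        nu = self.conditions[condition]
        for tf in self.tfs:
            if tf.name not in nu:
                raise ValidationError(
                    f"condition {condition!r} missing concentration for {tf.name}"
                )
            if nu[tf.name] < 0:
                raise ValidationError(
                    f"negative concentration for {tf.name} in {condition!r}"
                )
        return nu


@dataclass(frozen=True)
class Configuration:
    """One bound-site subset with its Boltzmann weight."""

    bound: tuple[int, ...]  # indices into the site list
    weight: float


@dataclass(frozen=True)
class OccupancyProfile:
    condition: str
    occupancies: tuple[float, ...]  # parallel to the site list

    def __post_init__(self):
        for o in self.occupancies:
            if not (-1e-12 <= o <= 1 + 1e-12):
                raise ValidationError(f"occupancy {o} outside [0,1]")


@dataclass(frozen=True)
class SiteActivityProfile:
    """Per-site contributions: activator barrier reduction α·O_eff (units of
    θ) and repressor fractional interaction-strength reduction β_R·O."""

    activator_activity: dict  # site index -> alpha * O_eff
    repressor_activity: dict  # site index -> beta_R * O


@dataclass(frozen=True)
class TranscriptionPrediction:
    interaction_strength: float
    interaction_strength_post: float
    rate: float
    fold_vs_promoter_only: float
    site_activity: SiteActivityProfile
    condition: str


def _site_weights(
    sites: Sequence[BindingSite], spec: ThermoModelSpec, condition: str
) -> np.ndarray:
    nu = spec.concentrations(condition)
    return np.array(
        [spec.tf(s.tf_name).binding_scale * s.q * nu[s.tf_name] for s in sites]
    )


def _coop_factor(
    a: BindingSite, b: BindingSite, spec: ThermoModelSpec
) -> float:
    """Cooperativity factor for adjacent bound pair (a before b)."""
    gap = b.start - a.end
    ca = spec.tf(a.tf_name).cooperativity
    if ca is not None and ca.partner == b.tf_name and 0 <= gap <= ca.max_gap:
        return ca.omega
    cb = spec.tf(b.tf_name).cooperativity
    if cb is not None and cb.partner == a.tf_name and 0 <= gap <= cb.max_gap:
        return cb.omega
    return 1.0


def enumerate_configurations(
    sites: Sequence[BindingSite], spec: ThermoModelSpec, condition: str
) -> list[Configuration]:
    """Brute-force ensemble: every subset of pairwise non-overlapping sites.

    Oracle for ``site_occupancies``; refuses instances above
    ``MAX_ENUM_SITES`` sites.
    """
    n = len(sites)
    if n > MAX_ENUM_SITES:
        raise OracleSizeError(
            f"{n} sites exceeds the enumeration guard ({MAX_ENUM_SITES}); "
            "use site_occupancies (dynamic programming) instead"
        )
    w = _site_weights(sites, spec, condition)
    order = sorted(range(n), key=lambda i: (sites[i].start, sites[i].end))
    configs = []
    for r in range(n + 1):
        for combo in itertools.combinations(order, r):
            ok = True
            for i, j in itertools.combinations(combo, 2):
                if sites[i].overlaps(sites[j]):
                    ok = False
                    break
            if not ok:
                continue
            weight = float(np.prod([w[i] for i in combo])) if combo else 1.0
            for a, b in zip(combo, combo[1:]):
                weight *= _coop_factor(sites[a], sites[b], spec)
            configs.append(Configuration(bound=tuple(combo), weight=weight))
    return configs


def site_occupancies(
    sites: Sequence[BindingSite], spec: ThermoModelSpec, condition: str
) -> OccupancyProfile:
    """Fractional occupancy of each site from the bound-configuration ensemble.

    O_i = (Σ weights of configurations containing i) / Z, computed by
    forward/backward dynamic programming over sites sorted by start; exact
    and linear-time in practice (quadratic worst case in site count).
    """
    n = len(sites)
    if n == 0:
        return OccupancyProfile(condition=condition, occupancies=())
    starts = [s.start for s in sites]
    if any(starts[i] > starts[i + 1] for i in range(n - 1)):
        raise ValidationError("sites must be sorted by start")
    w = _site_weights(sites, spec, condition)

    # f[j]: total weight of configurations of sites[0..j] in which j is the
    # right-most bound site; g[j]: total weight of completions to the right
    # of j given j is the previous bound site.
    f = np.zeros(n)
    for j in range(n):
        acc = 1.0
        for i in range(j):
            if sites[i].end <= sites[j].start:
                acc += f[i] * _coop_factor(sites[i], sites[j], spec)
        f[j] = w[j] * acc
    g = np.zeros(n)
    for j in range(n - 1, -1, -1):
        acc = 1.0
        for k in range(j + 1, n):
            if sites[j].end <= sites[k].start:
                acc += w[k] * _coop_factor(sites[j], sites[k], spec) * g[k]
        g[j] = acc
    # partition function: empty config + all configs grouped by right-most site
    z = 1.0 + float(f.sum())
    occ = np.clip(f * g / z, 0.0, 1.0)
    return OccupancyProfile(condition=condition, occupancies=tuple(float(o) for o in occ))


def interaction_strength(
    occ: OccupancyProfile,
    sites: Sequence[BindingSite],
    spec: ThermoModelSpec,
) -> tuple[float, float, SiteActivityProfile]:
    """Quenching-adjusted interaction strength and long-range repression.

    Returns (E, E′, per-site activity profile).
    """
    o = np.asarray(occ.occupancies)
    act_activity: dict[int, float] = {}
    rep_activity: dict[int, float] = {}
    repressors = [
        (j, s, spec.tf(s.tf_name))
        for j, s in enumerate(sites)
        if spec.tf(s.tf_name).role == "repressor"
    ]
    e = 0.0
    for i, s in enumerate(sites):
        tf = spec.tf(s.tf_name)
        if tf.role != "activator":
            continue
        o_eff = o[i]
        for j, rs, rtf in repressors:
            gap = max(rs.start - s.end, s.start - rs.end, 0)
            if gap <= rtf.quench_range:
                o_eff *= 1.0 - rtf.quenching_efficiency * o[j]
        o_eff = max(o_eff, 0.0)
        contrib = tf.activation_efficiency * o_eff
        act_activity[i] = contrib
        e += contrib
    e_post = e
    for j, rs, rtf in repressors:
        frac = rtf.longrange_efficiency * o[j]
        rep_activity[j] = frac
        e_post *= 1.0 - frac
    return e, e_post, SiteActivityProfile(act_activity, rep_activity)


def transcription_rate(e_post: float, spec: ThermoModelSpec) -> float:
    """Enzymatic initiation: r = R_max·exp(−max(0, θ − E′)).

    Basal rate R_max·e^(−θ) at E′ = 0; saturates at R_max once the
    interaction strength removes the whole barrier.
    """
    if e_post < 0:
        raise ValidationError("interaction strength must be >= 0")
    return spec.r_max * float(np.exp(-max(0.0, spec.theta - e_post)))


def assemble_construct(
    promoter: CRMRecord,
    distal: Optional[CRMRecord],
    spacer_bp: int = DEFAULT_SPACER_BP,
) -> CRMRecord:
    """Concatenate promoter, site-free spacer (N bases), and distal CRM into
    one coordinate frame, mirroring a reporter vector with the CRM placed
    beyond the transcription unit."""
    if distal is None:
        return CRMRecord(
            id=promoter.id, sequence=promoter.sequence, role="construct"
        )
    seq = promoter.sequence + "N" * spacer_bp + distal.sequence
    return CRMRecord(id=f"{promoter.id}+{distal.id}", sequence=seq, role="construct")


def predict_construct(
    promoter: CRMRecord,
    distal: Optional[CRMRecord],
    spec: ThermoModelSpec,
    matrices: Sequence[AlignmentMatrix],
    condition: str,
    spacer_bp: int = DEFAULT_SPACER_BP,
    q_min: float = DEFAULT_Q_MIN,
) -> TranscriptionPrediction:
    """Scan → occupancy → interaction strength → rate for one construct;
    fold is relative to the promoter alone in the same condition."""
    construct = assemble_construct(promoter, distal, spacer_bp)
    sites = scan_sites(construct, matrices, q_min)
    occ = site_occupancies(sites, spec, condition)
    e, e_post, activity = interaction_strength(occ, sites, spec)
    rate = transcription_rate(e_post, spec)

    prom_sites = scan_sites(
        CRMRecord(promoter.id, promoter.sequence, "construct"), matrices, q_min
    )
    prom_occ = site_occupancies(prom_sites, spec, condition)
    _, prom_e_post, _ = interaction_strength(prom_occ, prom_sites, spec)
    prom_rate = transcription_rate(prom_e_post, spec)
    return TranscriptionPrediction(
        interaction_strength=e,
        interaction_strength_post=e_post,
        rate=rate,
        fold_vs_promoter_only=rate / prom_rate,
        site_activity=activity,
        condition=condition,
    )


def predict_mutant_series(
    constructs: Sequence[tuple[str, CRMRecord, Optional[CRMRecord]]],
    spec: ThermoModelSpec,
    matrices: Sequence[AlignmentMatrix],
    conditions: Sequence[str],
    spacer_bp: int = DEFAULT_SPACER_BP,
    q_min: float = DEFAULT_Q_MIN,
) -> pd.DataFrame:
    """Fold vs promoter-only for each (construct, condition).

    ``constructs`` is a list of (label, promoter, distal-or-None); all share
    the model spec.  Folds are normalized to the promoter-only construct in
    each condition.
    """
    rows = []
    for label, promoter, distal in constructs:
        for cond in conditions:
            pred = predict_construct(
                promoter, distal, spec, matrices, cond, spacer_bp, q_min
            )
            rows.append(
                {
                    "construct": label,
                    "condition": cond,
                    "fold": pred.fold_vs_promoter_only,
                    "rate": pred.rate,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model-spec file


def load_model_spec(path) -> ThermoModelSpec:
    """Load a model specification from a YAML file.

    Layout::

        theta: 2.0
        r_max: 1.0
        tfs:
          - name: CebpA
            role: activator
            binding_scale: 1.0
            activation_efficiency: 1.5
          - name: Myb
            role: repressor
            quenching_efficiency: 0.8
            longrange_efficiency: 0.5
        conditions:
          uninduced: {CebpA: 1.0, Myb: 2.0}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: model spec must be a mapping")
    for key in ("theta", "tfs", "conditions"):
        if key not in raw:
            raise ValidationError(f"{path}: missing required field {key!r}")
    tfs = []
    for entry in raw["tfs"]:
        coop = entry.pop("cooperativity", None)
        if coop is not None:
            coop = Cooperativity(
                partner=coop["partner"],
                omega=float(coop["omega"]),
                max_gap=int(coop.get("max_gap", DEFAULT_COOP_GAP)),
            )
        try:
            tfs.append(TFSpec(cooperativity=coop, **entry))
        except TypeError as exc:
            raise ValidationError(f"{path}: bad TF entry {entry}: {exc}") from None
    return ThermoModelSpec(
        tfs=tuple(tfs),
        theta=float(raw["theta"]),
        r_max=float(raw.get("r_max", 1.0)),
        conditions=raw["conditions"],
    )
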