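"""Binding-site annotation and model-guided site-directed mutagenesis.

A transcription factor's binding preference is represented by an alignment
(count) matrix: per-position base counts from a collection of known sites.
Sites on a cis-regulatory module (CRM) are scored by their affinity relative
to the consensus sequence,

    q = prod_i p_i(b_i) / p_i(consensus_i),

with pseudocounted per-position frequencies ``p_i``, so q = 1 for the
consensus and q < 1 otherwise.  Mutagenesis follows the standard
site-ablation recipe: replace every position of a target site with the base
least favored by the matrix, falling back to the second-least-favored base
at positions where the primary choice would create new sites or perturb
neighboring ones.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_Q_MIN = 0.01
DEFAULT_PSEUDOCOUNT = 0.5


class ConfigurationError(ValueError):
    """Raised when inputs cannot define a valid scan or design."""


class MutationDesignError(RuntimeError):
    """Raised when no lowest/second-lowest substitution plan satisfies the
    design postconditions; carries the violating sites."""

    def __init__(self, message: str, violations: list["BindingSite"]):
        super().__init__(message)
        self.violations = violations


class PlanIntegrityError(ValueError):
    """Raised when a mutation plan does not match the sequence it is applied to."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentMatrix:
    """Per-position base counts for one TF, with pseudocounted frequencies."""

    tf_name: str
    counts: np.ndarray  # L x 4, columns A,C,G,T
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ConfigurationError(
                f"{self.tf_name}: counts must be L x 4, got {counts.shape}"
            )
        if counts.shape[0] < 4:
            raise ConfigurationError(f"{self.tf_name}: matrix length must be >= 4")
        if (counts < 0).any():
            raise ConfigurationError(f"{self.tf_name}: negative counts")
        if self.pseudocount < 0:
            raise ConfigurationError(f"{self.tf_name}: negative pseudocount")
        if (counts.sum(axis=1) + 4 * self.pseudocount <= 0).any():
            raise ConfigurationError(
                f"{self.tf_name}: zero column sum after pseudocount"
            )
        bg = np.asarray(self.background, dtype=float)
        if abs(bg.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"{self.tf_name}: background must sum to 1")
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        """Pseudocounted per-position base frequencies (rows sum to 1)."""
        c = self.counts + self.pseudocount
        return c / c.sum(axis=1, keepdims=True)

    @property
    def consensus(self) -> str:
        # argmax ties resolve to the alphabetically first base
        return "".join(BASES[i] for i in self.frequencies.argmax(axis=1))

    def site_affinity(self, site_seq: str) -> float:
        """Relative affinity q of ``site_seq`` (must be over ACGT)."""
        if len(site_seq) != len(self):
            raise ConfigurationError("site length does not match matrix length")
        f = self.frequencies
        cons = f.max(axis=1)
        q = 1.0
        for i, b in enumerate(site_seq):
            q *= f[i, _BASE_INDEX[b]] / cons[i]
        return q

    def lowest_bases(self, position: int, exclude: str) -> tuple[str, str]:
        """Least and second-least favored bases at ``position``, excluding
        ``exclude`` (the wildtype base); alphabetical tie-break."""
        f = self.frequencies[position]
        order = sorted(
            (b for b in BASES if b != exclude), key=lambda b: (f[_BASE_INDEX[b]], b)
        )
        return order[0], order[1]


@dataclass(frozen=True)
class CRMRecord:
    """A named DNA sequence with its role in the reporter construct."""

    id: str
    sequence: str
    role: str = "distal_crm"  # promoter | distal_crm | construct

    def __post_init__(self):
        seq = self.sequence.upper()
        if len(seq) < 1:
            raise ConfigurationError(f"{self.id}: empty sequence")
        if set(seq) - set("ACGTN"):
            raise ConfigurationError(f"{self.id}: sequence contains non-ACGTN bases")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BindingSite:
    """A strand-aware TF binding site located on a construct sequence.

    Coordinates are 0-based half-open on the forward strand; ``site_seq`` is
    read on the binding strand.
    """

    tf_name: str
    start: int
    end: int
    strand: str  # '+' or '-'
    site_seq: str
    q: float
    llr: float

    @property
    def key(self) -> tuple:
        return (self.tf_name, self.start, self.strand)

    def overlaps(self, other: "BindingSite") -> bool:
        return self.start < other.end and other.start < self.end

    def overlaps_interval(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass(frozen=True)
class MutationPlan:
    """Edits (forward-strand coordinates and bases) that ablate one site."""

    target_site: BindingSite
    edits: tuple[tuple[int, str, str], ...]
    fallback_positions: tuple[int, ...] = ()

    def __post_init__(self):
        for pos, old, new in self.edits:
            if not (self.target_site.start <= pos < self.target_site.end):
                raise ConfigurationError(f"edit at {pos} outside target site")
            if old == new:
                raise ConfigurationError(f"edit at {pos} does not change the base")


def scan_sites(
    crm: CRMRecord,
    matrices: Sequence[AlignmentMatrix],
    q_min: float = DEFAULT_Q_MIN,
) -> list[BindingSite]:
    """Annotate all binding sites with relative affinity q >= q_min.

    Both strands are scanned; windows containing N are skipped.  When forward
    and reverse hits of the same matrix share a start, only the better strand
    is kept (both are kept if starts differ).  Sites are sorted by start,
    then end, then TF name.
    """
    if not (0 < q_min <= 1):
        raise ConfigurationError("q_min must be in (0, 1]")
    if not matrices:
        raise ConfigurationError("no alignment matrices supplied")
    seq = crm.sequence
    sites: list[BindingSite] = []
    for mat in matrices:
        L = len(mat)
        if L > len(seq):
            continue
        f = mat.frequencies
        cons = f.max(axis=1)
        with np.errstate(divide="ignore"):  # zero-pseudocount matrices
            logf = np.log(f)
        logbg = np.log(np.asarray(mat.background))
        # integer-encode once; N -> -1 sentinel
        enc = np.frombuffer(seq.encode(), dtype=np.uint8)
        code = np.full(len(seq), -1, dtype=np.int64)
        for b, i in _BASE_INDEX.items():
            code[enc == ord(b)] = i
        best: dict[int, BindingSite] = {}
        # score all windows on both strands via strided gather
        windows = np.lib.stride_tricks.sliding_window_view(code, L)
        valid = (windows >= 0).all(axis=1)
        for strand in "+-":
            if strand == "+":
                w = windows
            else:
                # reverse strand: site read 3'->5' complemented (keep N sentinel)
                rev = windows[:, ::-1]
                w = np.where(rev >= 0, 3 - rev, -1)
            safe = np.where(w >= 0, w, 0)
            pos_idx = np.arange(L)
            logp = logf[pos_idx, safe].sum(axis=1)
            q_all = np.exp(logp - np.log(cons).sum())
            llr_all = logp - logbg[safe].sum(axis=1)
            hits = np.nonzero(valid & (q_all >= q_min))[0]
            for start in hits:
                start = int(start)
                window = seq[start : start + L]
                site_seq = window if strand == "+" else reverse_complement(window)
                site = BindingSite(
                    tf_name=mat.tf_name,
                    start=start,
                    end=start + L,
                    strand=strand,
                    site_seq=site_seq,
                    q=float(q_all[start]),
                    llr=float(llr_all[start]),
                )
                prev = best.get(start)
                if prev is None or site.q > prev.q:
                    best[start] = site
        sites.extend(best.values())
    sites.sort(key=lambda s: (s.start, s.end, s.tf_name, s.strand))
    return sites


def _matrix_by_name(matrices: Sequence[AlignmentMatrix], name: str) -> AlignmentMatrix:
    for m in matrices:
        if m.tf_name == name:
            return m
    raise ConfigurationError(f"no alignment matrix for TF {name!r}")


def _candidate_edits(
    crm: CRMRecord,
    target: BindingSite,
    matrix: AlignmentMatrix,
) -> list[tuple[int, str, str, str]]:
    """Per motif position: (forward position, old base, primary new base,
    fallback new base), all on the forward strand."""
    L = len(matrix)
    out = []
    for j in range(L):
        if target.strand == "+":
            pos = target.start + j
        else:
            pos = target.end - 1 - j
        old_fwd = crm.sequence[pos]
        # wildtype base in motif orientation
        old_motif = old_fwd if target.strand == "+" else old_fwd.translate(_COMPLEMENT)
        lo, lo2 = matrix.lowest_bases(j, exclude=old_motif)
        if target.strand == "-":
            lo = lo.translate(_COMPLEMENT)
            lo2 = lo2.translate(_COMPLEMENT)
        out.append((pos, old_fwd, lo, lo2))
    out.sort(key=lambda t: t[0])
    return out


def _check_postconditions(
    mutant: CRMRecord,
    crm: CRMRecord,
    target: BindingSite,
    matrices: Sequence[AlignmentMatrix],
    q_min: float,
    wt_sites: list[BindingSite],
) -> list[BindingSite]:
    """Return the list of postcondition-violating sites in the mutant scan
    (empty list means the plan is acceptable)."""
    target_matrix = _matrix_by_name(matrices, target.tf_name)
    mut_sites = scan_sites(mutant, matrices, q_min)
    violations: list[BindingSite] = []
    # (i) the target window must no longer score above threshold
    for strand_seq in (
        mutant.sequence[target.start : target.end],
        reverse_complement(mutant.sequence[target.start : target.end]),
    ):
        if target_matrix.site_affinity(strand_seq) >= q_min:
            violations.append(target)
            break
    wt_keys = {s.key for s in wt_sites}
    wt_by_key = {s.key: s for s in wt_sites}
    for s in mut_sites:
        if s.key not in wt_keys:
            # (ii) new site created anywhere
            violations.append(s)
        elif not s.overlaps(target) and abs(s.q - wt_by_key[s.key].q) > 1e-12:
            # (iii) non-overlapping wildtype site perturbed
            violations.append(s)
    return violations


def design_site_mutation(
    crm: CRMRecord,
    target: BindingSite,
    matrices: Sequence[AlignmentMatrix],
    q_min: float = DEFAULT_Q_MIN,
) -> MutationPlan:
    """Design substitutions ablating ``target`` without side effects.

    Every position of the site is changed to the base with the lowest
    pseudocounted frequency in the matrix (alphabetical tie-break, wildtype
    base excluded).  Where the all-lowest mutant creates a new site for any
    supplied matrix or perturbs a non-overlapping wildtype site, the
    second-lowest base is substituted at the interfering positions; the
    search tries fallback position subsets in order of increasing size and
    fails explicitly when none works.
    """
    matrix = _matrix_by_name(matrices, target.tf_name)
    cands = _candidate_edits(crm, target, matrix)
    wt_sites = scan_sites(crm, matrices, q_min)
    n = len(cands)
    last_violations: list[BindingSite] = []

    def build(fallback: frozenset[int]) -> MutationPlan:
        edits = []
        fb_positions = []
        for k, (pos, old, lo, lo2) in enumerate(cands):
            new = lo2 if k in fallback else lo
            if new == old:  # fallback collides with wildtype; skip edit
                continue
            edits.append((pos, old, new))
            if k in fallback:
                fb_positions.append(pos)
        return MutationPlan(
            target_site=target,
            edits=tuple(edits),
            fallback_positions=tuple(sorted(fb_positions)),
        )

    # subsets in order of increasing fallback count; cap the search
    max_subsets = 4096
    tried = 0
    for r in range(n + 1):
        for combo in itertools.combinations(range(n), r):
            tried += 1
            if tried > max_subsets:
                break
            plan = build(frozenset(combo))
            mutant = apply_mutation_plan(crm, plan)
            violations = _check_postconditions(
                mutant, crm, target, matrices, q_min, wt_sites
            )
            if not violations:
                return plan
            last_violations = violations
        if tried > max_subsets:
            break
    raise MutationDesignError(
        f"no lowest/second-lowest substitution plan ablates "
        f"{target.tf_name}@{target.start} without side effects; "
        f"violating sites: "
        + ", ".join(f"{v.tf_name}@{v.start}{v.strand}" for v in last_violations),
        last_violations,
    )


def apply_mutation_plan(crm: CRMRecord, plan: MutationPlan) -> CRMRecord:
    """Apply substitutions, returning a new record (length unchanged)."""
    seq = list(crm.sequence)
    for pos, old, new in plan.edits:
        if pos >= len(seq) or seq[pos] != old:
            raise PlanIntegrityError(
                f"edit {pos}:{old}->{new} does not match sequence "
                f"(found {seq[pos] if pos < len(seq) else 'EOS'}); "
                "plan was built on a different sequence"
            )
        seq[pos] = new
    mut_id = f"{crm.id}_mut" if plan.edits else crm.id
    return CRMRecord(id=mut_id, sequence="".join(seq), role=crm.role)


# ---------------------------------------------------------------------------
# File formats


def read_fasta(path) -> list[CRMRecord]:
    """Read CRM/construct records; a ``role=`` token in the description sets
    the role (default distal_crm)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        role = "distal_crm"
        for token in rec.description.split():
            if token.startswith("role="):
                role = token.split("=", 1)[1]
        records.append(CRMRecord(id=rec.id, sequence=str(rec.seq), role=role))
    return records


def write_fasta(records: Iterable[CRMRecord], path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=f"role={r.role}")
        for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_count_matrix(path, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> AlignmentMatrix:
    """Read a plain-text count matrix.

    Two dialects are accepted: JASPAR-style (4 rows labelled A/C/G/T, an
    optional ``>name`` header, optional brackets) and TRANSFAC-style (a
    position-per-row table with columns A C G T, optional leading position
    index, optional ID/PO/XX lines).
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    name = None
    rows: list[tuple[str | None, list[float]]] = []
    for ln in lines:
        if ln.startswith(">"):
            name = ln[1:].split()[0]
            continue
        up = ln.split()
        if up[0] in ("ID", "NA"):
            name = up[-1]
            continue
        if up[0] in ("XX", "PO", "P0", "BF", "//", "CC", "DE", "AC"):
            continue
        label = None
        fields = up
        head = up[0].rstrip(":").upper()
        if head in ("A", "C", "G", "T"):
            label = head
            fields = up[1:]
        vals = []
        for tok in fields:
            tok = tok.strip("[]")
            if not tok:
                continue
            try:
                vals.append(float(tok))
            except ValueError:
                vals = []
                break
        if vals:
            rows.append((label, vals))
    if not rows:
        raise ConfigurationError(f"{path}: no numeric matrix rows found")
    labels = [r[0] for r in rows]
    if all(l in ("A", "C", "G", "T") for l in labels) and len(rows) == 4:
        # JASPAR: rows are bases, columns positions
        by_base = {l: v for l, v in rows}
        counts = np.array([by_base[b] for b in BASES]).T
    else:
        # TRANSFAC: rows are positions; drop a leading index column if present
        mat = [v for _, v in rows]
        width = len(mat[0])
        if any(len(v) != width for v in mat):
            raise ConfigurationError(f"{path}: ragged matrix rows")
        arr = np.array(mat)
        if width == 5:
            arr = arr[:, 1:]
        elif width != 4:
            raise ConfigurationError(f"{path}: expected 4 (or 5) columns, got {width}")
        counts = arr
    if name is None:
        import os

        name = os.path.splitext(os.path.basename(str(path)))[0]
    return AlignmentMatrix(tf_name=name, counts=counts, pseudocount=pseudocount)


def write_count_matrix(matrix: AlignmentMatrix, path) -> None:
    """Write the canonical (JASPAR-style) form."""
    with open(path, "w") as fh:
        fh.write(f">{matrix.tf_name}\n")
        for i, b in enumerate(BASES):
            vals = " ".join(f"{v:g}" for v in matrix.counts[:, i])
            fh.write(f"{b} [ {vals} ]\n")


def sites_to_bed(sites: Sequence[BindingSite], construct_id: str) -> str:
    """BED-like TSV: construct, start, end, strand, tf, q."""
    lines = ["construct\tstart\tend\tstrand\ttf\tq"]
    for s in sites:
        lines.append(
            f"{construct_id}\t{s.start}\t{s.end}\t{s.strand}\t{s.tf_name}\t{s.q:.6g}"
        )
    return "\n".join(lines) + "\n"
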