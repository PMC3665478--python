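"""Per-position residue-frequency profiles from E-value-filtered alignments.

The profile for a query protein is built once from all of its pairwise
alignment hits (E < 1e-9 by default) and then sliced per variant into the five
profile features: mutant-residue frequency, wild-type frequency, per-position
aligned-sequence depth, whole-alignment depth, and the conservation index of
the position.  Depth counts are saturation-scaled as n/(n+K) so the SVM sees
bounded inputs.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Iterable, TextIO, Union

import numpy as np

from .errors import FormatError, IntegrityError, LookupFailure
from .io_formats import ProteinRecord, VariantRecord, _as_stream
from .residues import AA_INDEX

DEFAULT_E_MAX = 1e-9
DEPTH_SCALE_K = 100.0


def saturation_scale(n: float, k: float = DEPTH_SCALE_K) -> float:
    """Map an unbounded count into [0,1) as n/(n+k)."""
    if n < 0:
        raise ValueError(f"count must be >= 0, got {n}")
    return n / (n + k)


@dataclass(frozen=True)
class AlignmentRecord:
    """One pairwise hit against the query.

    ``q_start``/``q_end`` are 1-based inclusive coordinates on the query;
    aligned strings carry gaps as ``-`` and have equal length.
    """

    subject_id: str
    e_value: float
    q_start: int
    q_end: int
    q_aln: str
    s_aln: str

    def __post_init__(self) -> None:
        if len(self.q_aln) != len(self.s_aln):
            raise IntegrityError(
                f"hit {self.subject_id}: aligned strings differ in length"
            )
        if self.q_start < 1 or self.q_end < self.q_start:
            raise IntegrityError(f"hit {self.subject_id}: bad query segment")


@dataclass
class SequenceProfile:
    """L x 20 residue frequencies plus per-position and total depth."""

    frequencies: np.ndarray  # shape (L, 20); rows sum to 1 where depth > 0
    n_pos: np.ndarray  # per-position aligned-sequence depth (query counted)
    n_all: int  # total sequences in the alignment (query counted)

    def __post_init__(self) -> None:
        L = self.frequencies.shape[0]
        if self.frequencies.shape != (L, 20):
            raise IntegrityError("frequency matrix must be L x 20")
        if self.n_pos.shape != (L,):
            raise IntegrityError("n_pos must have one entry per position")
        sums = self.frequencies.sum(axis=1)
        if not np.all((np.abs(sums - 1) < 1e-9) | (np.abs(sums) < 1e-9)):
            raise IntegrityError("profile rows must sum to 0 or 1")
        if np.any(self.n_pos > self.n_all):
            raise IntegrityError("per-position depth exceeds total depth")

    def __len__(self) -> int:
        return self.frequencies.shape[0]

    def frequency(self, pos: int, residue: str) -> float:
        """Frequency of ``residue`` at 1-based position ``pos``."""
        self._check_pos(pos)
        idx = AA_INDEX.get(residue)
        if idx is None:
            return 0.0
        return float(self.frequencies[pos - 1, idx])

    def _check_pos(self, pos: int) -> None:
        if not 1 <= pos <= len(self):
            raise LookupFailure(f"position {pos} outside profile length {len(self)}")


def build_profile(
    query: ProteinRecord,
    hits: Iterable[AlignmentRecord],
    e_max: float = DEFAULT_E_MAX,
) -> SequenceProfile:
    """Tally residue counts per query position over E-value-filtered hits.

    Hits with E >= ``e_max`` are excluded (strictly-below rule).  The query
    itself is always counted.  Gap characters and ambiguity codes contribute
    to neither the counts nor the per-position depth.
    """
    L = len(query.sequence)
    counts = np.zeros((L, 20), dtype=float)
    depth = np.zeros(L, dtype=int)
    # The query sequence is row zero of the implicit alignment.
    for i, aa in enumerate(query.sequence):
        idx = AA_INDEX.get(aa)
        if idx is not None:
            counts[i, idx] += 1
            depth[i] += 1
    n_all = 1
    for hit in hits:
        if hit.e_value >= e_max:
            continue
        _check_hit_consistency(query, hit)
        n_all += 1
        qpos = hit.q_start - 1  # 0-based cursor on the query
        for qc, sc in zip(hit.q_aln, hit.s_aln):
            if qc == "-":
                continue
            idx = AA_INDEX.get(sc.upper())
            if idx is not None:
                counts[qpos, idx] += 1
                depth[qpos] += 1
            qpos += 1
    frequencies = np.zeros_like(counts)
    nonzero = depth > 0
    frequencies[nonzero] = counts[nonzero] / depth[nonzero, None]
    return SequenceProfile(frequencies=frequencies, n_pos=depth, n_all=n_all)


def _check_hit_consistency(query: ProteinRecord, hit: AlignmentRecord) -> None:
    ungapped = hit.q_aln.replace("-", "").upper()
    segment = query.sequence[hit.q_start - 1 : hit.q_end]
    if ungapped != segment:
        raise IntegrityError(
            f"hit {hit.subject_id}: aligned query segment disagrees with the "
            f"query sequence over [{hit.q_start},{hit.q_end}]"
        )


def conservation_index(profile: SequenceProfile, pos: int) -> float:
    """CI = 1 - H(pos)/log2(20) from the Shannon entropy of the column.

    A fully conserved column scores 1, a uniform column 0; a zero-depth
    column is defined as 0.
    """
    profile._check_pos(pos)
    row = profile.frequencies[pos - 1]
    if profile.n_pos[pos - 1] == 0:
        return 0.0
    nz = row[row > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return 1.0 - entropy / math.log2(20)


@dataclass(frozen=True)
class ProfileFeatures:
    """The five profile-derived SVM inputs, in fixed order."""

    f_mut: float
    f_wt: float
    n_pos_scaled: float
    n_all_scaled: float
    ci: float

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.f_mut, self.f_wt, self.n_pos_scaled, self.n_all_scaled, self.ci)


def profile_features(
    profile: SequenceProfile,
    variant: VariantRecord,
    depth_scale_k: float = DEPTH_SCALE_K,
) -> ProfileFeatures:
    """Slice a protein profile at the variant position.

    Order: (f_mut, f_wt, scaled per-position depth, scaled total depth, CI);
    this order is versioned in the feature-layout tag.
    """
    profile._check_pos(variant.pos)
    return ProfileFeatures(
        f_mut=profile.frequency(variant.pos, variant.mut),
        f_wt=profile.frequency(variant.pos, variant.wt),
        n_pos_scaled=saturation_scale(float(profile.n_pos[variant.pos - 1]), depth_scale_k),
        n_all_scaled=saturation_scale(float(profile.n_all), depth_scale_k),
        ci=conservation_index(profile, variant.pos),
    )


# ---------------------------------------------------------------------------
# Hit-file readers
# ---------------------------------------------------------------------------

def read_alignment_hits(source: Union[str, TextIO]) -> list[AlignmentRecord]:
    """Tabular hit file: subject, e_value, q_start, q_end, q_aln, s_aln.

    Tab-separated with a header line; compatible with common pairwise
    alignment exports after column selection.
    """
    hits: list[AlignmentRecord] = []
    lines = _as_stream(source).read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#") or line.lower().startswith("subject"):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise FormatError(f"hit line {lineno}: expected 6 columns")
        hits.append(
            AlignmentRecord(
                subject_id=parts[0].strip(),
                e_value=float(parts[1]),
                q_start=int(parts[2]),
                q_end=int(parts[3]),
                q_aln=parts[4].strip(),
                s_aln=parts[5].strip(),
            )
        )
    return hits


def write_alignment_hits(hits: Iterable[AlignmentRecord]) -> str:
    out = ["subject\te_value\tq_start\tq_end\tq_aln\ts_aln"]
    for h in hits:
        out.append(
            f"{h.subject_id}\t{h.e_value:.3g}\t{h.q_start}\t{h.q_end}\t{h.q_aln}\t{h.s_aln}"
        )
    return "\n".join(out) + "\n"


def hits_from_aligned_fasta(source: Union[str, TextIO]) -> tuple[ProteinRecord, list[AlignmentRecord]]:
    """Read an aligned multi-FASTA (query first; no E-value filtering).

    Every non-query row becomes a full-length hit with E-value 0 so it always
    survives the threshold.
    """
    from Bio import SeqIO

    rows = [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(_as_stream(source), "fasta")
    ]
    if not rows:
        raise FormatError("aligned FASTA is empty")
    query_aln = rows[0][1]
    query_seq = query_aln.replace("-", "")
    query = ProteinRecord(id=rows[0][0], sequence=query_seq)
    hits: list[AlignmentRecord] = []
    for row_id, row_seq in rows[1:]:
        if len(row_seq) != len(query_aln):
            raise IntegrityError(f"aligned row {row_id} length mismatch")
        # Project out query-gap columns so coordinates live on the query.
        q_chars, s_chars = [], []
        for qc, sc in zip(query_aln, row_seq):
            if qc == "-":
                continue
            q_chars.append(qc)
            s_chars.append(sc)
        hits.append(
            AlignmentRecord(
                subject_id=row_id,
                e_value=0.0,
                q_start=1,
                q_end=len(query_seq),
                q_aln="".join(q_chars),
                s_aln="".join(s_chars),
            )
        )
    return query, hits
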