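"""Position-specific profile models and affine-gap local alignment.

A :class:`ProfileModel` is a per-column log-odds matrix in bits built from a
seed alignment with background-proportional pseudocounts:

    log_odds(c, a) = log2( ((n_ca + a*q_a) / (N_c + a)) / q_a )

where ``n_ca`` counts residue ``a`` in column ``c`` (gaps and ``X``
excluded), ``N_c`` is the column's residue count, ``a`` the pseudocount
weight and ``q_a`` the background frequency.  ``X`` in a query scores 0 bits
at every column (background-neutral).

Sequences are scored by Smith-Waterman-style local alignment against the
profile columns under affine gap penalties (a gap of length L costs
``gap_open + (L-1) * gap_extend`` bits).  This is a deterministic,
oracle-testable stand-in for profile-HMM bit scores; the conventional
acceptance threshold of 20 bits is carried as the default cutoff but is not
numerically comparable to HMMER scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import DegenerateAlignmentError, ParseError, UnanchorableError, ValidationError
from .io_formats import AMINO_ACIDS, GAP, Msa, ProteinSequence, SUBDOMAIN_IDS

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_X_INDEX = 20  # column 20 of the score matrix, fixed at 0 bits

#: numerical tolerance used when retracing equal-valued DP predecessors
_TRACE_TOL = 1e-9


def encode(residues: str) -> np.ndarray:
    """Map a residue string to integer codes (X -> 20)."""
    return np.fromiter(
        (_AA_INDEX.get(ch, _X_INDEX) for ch in residues), dtype=np.int64, count=len(residues)
    )


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20.0)


@dataclass
class ProfileModel:
    """Per-column log-odds profile with affine gap penalties.

    ``log_odds`` has shape (length, 21); column index 20 is the score of the
    unknown residue ``X`` and is identically 0.
    """

    name: str
    log_odds: np.ndarray
    background: np.ndarray
    gap_open: float = 11.0
    gap_extend: float = 1.0
    cutoff_bits: float = 20.0
    subdomains: dict[str, tuple[int, int]] | None = field(default=None)

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.log_odds.ndim != 2 or self.log_odds.shape[1] != 21:
            raise ValidationError("log_odds must have shape (length, 21)")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValidationError("background frequencies must sum to 1")
        if not np.all(self.log_odds[:, _X_INDEX] == 0.0):
            raise ValidationError("score of 'X' must be 0 bits at every column")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValidationError("gap penalties must be nonnegative")
        if self.cutoff_bits < 0:
            raise ValidationError("cutoff_bits must be nonnegative")

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]

    def consensus(self) -> str:
        """Highest-scoring residue per column (ties by alphabet)."""
        return "".join(AMINO_ACIDS[int(np.argmax(self.log_odds[c, :20]))] for c in range(self.length))


@dataclass
class AlignmentResult:
    """One optimal local alignment of a sequence against a profile."""

    score_bits: float
    seq_interval: tuple[int, int]
    profile_interval: tuple[int, int]
    column_map: list[tuple[int, int]]  # (profile column, sequence index), strictly increasing

    def matched_columns(self) -> dict[int, int]:
        return dict(self.column_map)


@dataclass
class SubdomainAnchors:
    """Per-sequence residue intervals of the Hanks subdomains (I..XI).

    ``intervals[sd]`` is a half-open residue interval or ``None`` when the
    alignment did not cover that subdomain (e.g. a truncated domain).
    """

    seq_id: str
    intervals: dict[str, tuple[int, int] | None]

    def get(self, subdomain: str) -> tuple[int, int] | None:
        return self.intervals.get(subdomain)

    def n_present(self) -> int:
        return sum(1 for v in self.intervals.values() if v is not None)

    def complete(self) -> bool:
        return all(self.intervals.get(sd) is not None for sd in SUBDOMAIN_IDS)


def trim_columns(msa: Msa, max_gap_fraction: float) -> Msa:
    """Keep exactly the columns whose gap fraction is <= ``max_gap_fraction``.

    Subdomain annotation intervals are remapped onto the surviving columns;
    row order is preserved.  Raises :class:`DegenerateAlignmentError` when no
    column survives.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValidationError("max_gap_fraction must be in [0, 1]")
    nrow = msa.nrow
    keep: list[int] = []
    for c in range(msa.ncol):
        gaps = sum(1 for _, aligned in msa.rows if aligned[c] == GAP)
        if gaps / nrow <= max_gap_fraction:
            keep.append(c)
    if not keep:
        raise DegenerateAlignmentError(
            f"all {msa.ncol} columns exceed gap fraction {max_gap_fraction}"
        )
    keep_arr = np.asarray(keep)
    rows = [(rid, "".join(aligned[c] for c in keep)) for rid, aligned in msa.rows]
    ann = None
    if msa.subdomain_annotation is not None:
        ann = {}
        for sd, (start, end) in msa.subdomain_annotation.items():
            new_start = int(np.searchsorted(keep_arr, start))
            new_end = int(np.searchsorted(keep_arr, end))
            ann[sd] = (new_start, new_end)
    return Msa(rows, subdomain_annotation=ann)


def build_profile(
    msa: Msa,
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    cutoff_bits: float = 20.0,
    name: str = "profile",
) -> ProfileModel:
    """Build a log-odds profile from a seed alignment.

    Gaps and ``X`` are excluded from the counts.  A column with no residues
    at all is rejected with a pointer to :func:`trim_columns`.
    """
    if pseudocount_weight <= 0:
        raise ValidationError("pseudocount_weight must be > 0")
    q = uniform_background() if background is None else np.asarray(background, dtype=float)
    if q.shape != (20,) or abs(q.sum() - 1.0) > 1e-9 or np.any(q <= 0):
        raise ValidationError("background must be a positive length-20 distribution")
    ncol = msa.ncol
    counts = np.zeros((ncol, 20))
    for _, aligned in msa.rows:
        codes = encode(aligned.replace(GAP, "X"))  # gap -> X -> ignored below
        for c, code in enumerate(codes):
            if code < 20:
                counts[c, code] += 1
    n_c = counts.sum(axis=1)
    if np.any(n_c == 0):
        bad = int(np.argmin(n_c))
        raise DegenerateAlignmentError(
            f"column {bad} has no residues; trim the alignment first (trim_columns)"
        )
    freqs = (counts + pseudocount_weight * q) / (n_c + pseudocount_weight)[:, None]
    log_odds = np.zeros((ncol, 21))
    log_odds[:, :20] = np.log2(freqs / q)
    return ProfileModel(
        name=name,
        log_odds=log_odds,
        background=q,
        gap_open=gap_open,
        gap_extend=gap_extend,
        cutoff_bits=cutoff_bits,
        subdomains=dict(msa.subdomain_annotation) if msa.subdomain_annotation else None,
    )


def _dp_matrices(profile: ProfileModel, codes: np.ndarray):
    """Fill the three Gotoh matrices (match M, profile-column-skip X, residue-skip Y).

    Row-vectorised over profile columns; the within-row recurrence for X
    (gaps in the sequence, i.e. skipped profile columns) is solved with a
    prefix-max over ``M + j*gap_extend``.
    """
    n = len(codes)
    m = profile.length
    open_, ext = profile.gap_open, profile.gap_extend
    neg = -np.inf
    M = np.full((n + 1, m + 1), neg)
    Xm = np.full((n + 1, m + 1), neg)
    Ym = np.full((n + 1, m + 1), neg)
    if n == 0 or m == 0:
        return M, Xm, Ym
    scores = profile.log_odds  # (m, 21)
    jext = np.arange(m + 1) * ext
    for i in range(1, n + 1):
        srow = scores[:, codes[i - 1]]  # (m,)
        prev_best = np.maximum(np.maximum(M[i - 1], Xm[i - 1]), np.maximum(Ym[i - 1], 0.0))
        M[i, 1:] = prev_best[:-1] + srow
        Ym[i, 1:] = np.maximum(M[i - 1, 1:] - open_, Ym[i - 1, 1:] - ext)
        c = M[i] + jext  # X[i][j] = max_{k<=j-1} M[i][k] - open - (j-1-k)*ext
        run = np.maximum.accumulate(c)
        Xm[i, 1:] = run[:-1] - open_ - jext[:-1]
    return M, Xm, Ym


def score_local(profile: ProfileModel, seq: ProteinSequence | str) -> AlignmentResult:
    """Optimal local alignment of ``seq`` against the profile columns.

    Returns the maximal bit score (>= 0 by local-alignment convention) and
    one optimal trace; ties are broken deterministically preferring
    match > profile-gap (unmatched residue) > sequence-gap (skipped column),
    and the start cell with the smallest sequence index.
    """
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    codes = encode(residues)
    n, m = len(codes), profile.length
    if n == 0 or m == 0:
        return AlignmentResult(0.0, (0, 0), (0, 0), [])
    M, Xm, Ym = _dp_matrices(profile, codes)
    best = float(M.max())
    if best <= 0.0:
        return AlignmentResult(0.0, (0, 0), (0, 0), [])
    # deterministic argmax: smallest sequence index, then smallest column
    flat = np.argwhere(M >= best - _TRACE_TOL)
    i, j = (int(flat[0][0]), int(flat[0][1]))
    open_, ext = profile.gap_open, profile.gap_extend
    column_map: list[tuple[int, int]] = []
    state = "M"
    end_i, end_j = i, j
    tol = _TRACE_TOL
    while True:
        if state == "M":
            column_map.append((j - 1, i - 1))
            s = profile.log_odds[j - 1, codes[i - 1]]
            need = M[i, j] - s
            i, j = i - 1, j - 1
            if need <= tol:  # local start
                break
            if abs(M[i, j] - need) <= tol:
                state = "M"
            elif abs(Ym[i, j] - need) <= tol:
                state = "Y"
            elif abs(Xm[i, j] - need) <= tol:
                state = "X"
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback lost (M)")
        elif state == "Y":  # unmatched residue: consume sequence position i-1
            need = Ym[i, j]
            if abs(M[i - 1, j] - open_ - need) <= tol:
                state = "M"
            elif abs(Ym[i - 1, j] - ext - need) <= tol:
                state = "Y"
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback lost (Y)")
            i -= 1
        else:  # state == "X": skipped profile column j-1
            need = Xm[i, j]
            if abs(M[i, j - 1] - open_ - need) <= tol:
                state = "M"
            elif abs(Xm[i, j - 1] - ext - need) <= tol:
                state = "X"
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback lost (X)")
            j -= 1
    column_map.reverse()
    start_j, start_i = column_map[0]
    return AlignmentResult(
        score_bits=best,
        seq_interval=(start_i, end_i),
        profile_interval=(start_j, end_j),
        column_map=column_map,
    )


def score_only(profile: ProfileModel, seq: ProteinSequence | str) -> float:
    """Optimal local alignment score without a traceback (fast path)."""
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    codes = encode(residues)
    if len(codes) == 0 or profile.length == 0:
        return 0.0
    M, _, _ = _dp_matrices(profile, codes)
    return float(max(M.max(), 0.0))


def anchor_subdomains(reference: ProfileModel, seq: ProteinSequence) -> SubdomainAnchors:
    """Locate the 11 Hanks subdomains on a sequence via the reference profile.

    Each annotated column interval is mapped through the optimal local
    alignment's column map; subdomains with no matched column are reported
    absent.  Raises :class:`UnanchorableError` when the alignment score is
    below the profile cutoff (the sequence is not kinase-like).
    """
    if not reference.subdomains:
        raise ValidationError("reference profile carries no subdomain annotation")
    aln = score_local(reference, seq)
    if aln.score_bits < reference.cutoff_bits:
        raise UnanchorableError(
            f"{seq.id}: score {aln.score_bits:.1f} bits below cutoff {reference.cutoff_bits}"
        )
    intervals: dict[str, tuple[int, int] | None] = {}
    cmap = aln.column_map
    for sd, (start, end) in reference.subdomains.items():
        hits = [si for (col, si) in cmap if start <= col < end]
        intervals[sd] = (min(hits), max(hits) + 1) if hits else None
    return SubdomainAnchors(seq_id=seq.id, intervals=intervals)


def project_to_columns(profile: ProfileModel, seq: ProteinSequence) -> str:
    """Render a sequence as one aligned row over the profile's columns.

    Matched columns carry the matched residue, skipped columns a gap;
    residues falling between matches (insertions relative to the profile)
    are dropped.  Used for template-anchored alignment of new family
    members.
    """
    aln = score_local(profile, seq)
    row = [GAP] * profile.length
    for col, si in aln.column_map:
        row[col] = seq.residues[si]
    return "".join(row)


# ---------------------------------------------------------------------------
# serialization: versioned plain-text profile format

_FORMAT_TAG = "kinscan-profile"
_FORMAT_VERSION = "1"


def write_profile(profile: ProfileModel, path: str | Path) -> None:
    lines = [f"#{_FORMAT_TAG} v{_FORMAT_VERSION}"]
    lines.append(f"name\t{profile.name}")
    lines.append(f"length\t{profile.length}")
    lines.append(f"alphabet\t{AMINO_ACIDS}")
    lines.append("background\t" + " ".join(f"{x:.10g}" for x in profile.background))
    lines.append(f"gap_open\t{profile.gap_open:.10g}")
    lines.append(f"gap_extend\t{profile.gap_extend:.10g}")
    lines.append(f"cutoff_bits\t{profile.cutoff_bits:.10g}")
    if profile.subdomains:
        parts = [f"{sd}:{s}-{e}" for sd, (s, e) in profile.subdomains.items()]
        lines.append("subdomains\t" + ",".join(parts))
    for c in range(profile.length):
        lines.append(" ".join(f"{x:.10g}" for x in profile.log_odds[c, :20]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile(path: str | Path) -> ProfileModel:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith(f"#{_FORMAT_TAG} v"):
        raise ParseError(f"{path}: not a {_FORMAT_TAG} file")
    version = lines[0].split("v", 1)[1].strip()
    if version != _FORMAT_VERSION:
        raise ParseError(f"{path}: unsupported profile format version {version!r}")
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    for line in lines[1:]:
        if not line.strip():
            continue
        if "\t" in line and not rows:
            key, value = line.split("\t", 1)
            header[key] = value
        else:
            rows.append([float(x) for x in line.split()])
    try:
        length = int(header["length"])
        background = np.array([float(x) for x in header["background"].split()])
        gap_open = float(header["gap_open"])
        gap_extend = float(header["gap_extend"])
        cutoff = float(header["cutoff_bits"])
        name = header["name"]
    except KeyError as exc:
        raise ParseError(f"{path}: missing header field {exc}") from exc
    if len(rows) != length or any(len(r) != 20 for r in rows):
        raise ParseError(f"{path}: expected {length} rows of 20 scores")
    subdomains = None
    if "subdomains" in header:
        subdomains = {}
        for part in header["subdomains"].split(","):
            sd, span = part.split(":")
            s, e = span.split("-")
            subdomains[sd] = (int(s), int(e))
    log_odds = np.zeros((length, 21))
    log_odds[:, :20] = np.array(rows)
    return ProfileModel(
        name=name,
        log_odds=log_odds,
        background=background,
        gap_open=gap_open,
        gap_extend=gap_extend,
        cutoff_bits=cutoff,
        subdomains=subdomains,
    )


def rescaled(profile: ProfileModel, k: float) -> ProfileModel:
    """Profile with all scores and gap penalties multiplied by ``k`` > 0."""
    if k <= 0:
        raise ValidationError("scale factor must be positive")
    lo = profile.log_odds * k
    lo[:, _X_INDEX] = 0.0
    return replace(
        profile,
        log_odds=lo,
        gap_open=profile.gap_open * k,
        gap_extend=profile.gap_extend * k,
        cutoff_bits=profile.cutoff_bits * k,
    )
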