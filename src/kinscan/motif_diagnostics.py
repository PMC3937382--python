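"""Degenerate motif matching, TK-activity diagnostics, motif discovery and
sequence-logo column statistics.

Motifs use the field's degenerate notation: uppercase residues are fixed,
``X`` is a wildcard, ``(A/B)`` is an allowed set, and ``(X)6`` / ``(X)_6_``
expand to six wildcards.  The three default diagnostic rules encode the
classical tyrosine-kinase signatures: ``DL(R/A)A(A/R)N`` in the catalytic
loop (subdomain VI) with the substrate-site-stabilising key residues,
``XP(I/V)(K/R)W(T/M)APE`` in subdomain VIII with the substrate-recognition
proline, and ``GXR(M/L)`` in subdomain X whose fourth position is M or L in
TKs but P in the fungal FslK lineage.

A sequence is judged ``TK-like`` only when all three motifs are found and
every key residue checks out; a truncated domain (any required subdomain
window missing) is ``indeterminate``; everything else is ``non-TK``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import ParseError, ValidationError
from .io_formats import AMINO_ACIDS, GAP, Msa, ProteinSequence, SUBDOMAIN_IDS
from .profile_model import SubdomainAnchors

Element = frozenset | None  # None = wildcard; frozenset of residues otherwise
KeyStatus = Literal["pass", "fail", "absent"]


class _Absent:
    """Sentinel returned by scan_window when the subdomain itself is missing."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "ABSENT"

    def __bool__(self) -> bool:
        return False


ABSENT = _Absent()


@dataclass(frozen=True)
class MotifPattern:
    """An ordered degenerate motif anchored to a Hanks subdomain."""

    name: str
    elements: tuple[Element, ...]
    subdomain: str | None = None

    def __post_init__(self) -> None:
        if len(self.elements) < 2:
            raise ValidationError(f"motif {self.name!r}: length must be >= 2")
        for el in self.elements:
            if el is not None:
                if not el or not set(el) <= set(AMINO_ACIDS):
                    raise ValidationError(f"motif {self.name!r}: illegal allowed-set {el!r}")
        if self.subdomain is not None and self.subdomain not in SUBDOMAIN_IDS:
            raise ValidationError(f"motif {self.name!r}: unknown subdomain {self.subdomain!r}")

    def __len__(self) -> int:
        return len(self.elements)

    def to_text(self) -> str:
        """Render back into the degenerate notation."""
        parts = []
        for el in self.elements:
            if el is None:
                parts.append("X")
            elif len(el) == 1:
                parts.append(next(iter(el)))
            else:
                parts.append("(" + "/".join(sorted(el)) + ")")
        return "".join(parts)


def parse_pattern(text: str, subdomain: str | None = None, name: str | None = None) -> MotifPattern:
    """Parse the degenerate motif notation into a :class:`MotifPattern`.

    Raises :class:`ParseError` with a character offset on malformed input.
    """
    elements: list[Element] = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "X":
            elements.append(None)
            i += 1
        elif ch in AMINO_ACIDS:
            elements.append(frozenset(ch))
            i += 1
        elif ch == "(":
            close = text.find(")", i)
            if close < 0:
                raise ParseError(f"pattern {text!r}: unclosed '(' at offset {i}")
            body = text[i + 1 : close]
            i = close + 1
            if body == "X":
                # optional repeat: (X)6 or (X)_6_
                repeat, i = _parse_repeat(text, i)
                if repeat == 0:
                    raise ParseError(f"pattern {text!r}: zero repeat at offset {i}")
                elements.extend([None] * repeat)
            else:
                residues = body.split("/")
                if not all(len(r) == 1 and r in AMINO_ACIDS for r in residues):
                    raise ParseError(
                        f"pattern {text!r}: illegal allowed-set ({body}) at offset {close}"
                    )
                elements.append(frozenset(residues))
        else:
            raise ParseError(f"pattern {text!r}: illegal character {ch!r} at offset {i}")
    return MotifPattern(name=name or text, elements=tuple(elements), subdomain=subdomain)


def _parse_repeat(text: str, i: int) -> tuple[int, int]:
    """Parse an optional repeat count after ``(X)``; returns (count, next offset)."""
    n = len(text)
    underscored = i < n and text[i] == "_"
    if underscored:
        i += 1
    start = i
    while i < n and text[i].isdigit():
        i += 1
    if start == i:
        if underscored:
            raise ParseError(f"pattern {text!r}: expected digits after '_' at offset {start}")
        return 1, i  # bare (X) is a single wildcard
    count = int(text[start:i])
    if underscored:
        if i >= n or text[i] != "_":
            raise ParseError(f"pattern {text!r}: expected closing '_' at offset {i}")
        i += 1
    return count, i


def match_at(pattern: MotifPattern, window: str) -> bool:
    """Elementwise degenerate match of a window against a pattern.

    Wildcards accept everything including ``X``; fixed residues and
    allowed sets reject ``X`` (an unknown residue cannot confirm a
    diagnostic residue).
    """
    if len(window) != len(pattern):
        raise ValidationError(
            f"window length {len(window)} != pattern length {len(pattern)}"
        )
    for el, ch in zip(pattern.elements, window):
        if el is not None and ch not in el:
            return False
    return True


def scan_window(
    seq: ProteinSequence | str,
    anchors: SubdomainAnchors,
    pattern: MotifPattern,
    slack: int = 5,
):
    """Leftmost match position of a motif inside its subdomain window +- slack.

    Returns the 0-based start position, ``None`` when the window is present
    but the motif does not match, or :data:`ABSENT` when the subdomain was
    not anchored (truncated hit).
    """
    if pattern.subdomain is None:
        raise ValidationError(f"motif {pattern.name!r} has no subdomain to scan")
    interval = anchors.get(pattern.subdomain)
    if interval is None:
        return ABSENT
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    lo = max(0, interval[0] - slack)
    hi = min(len(residues), interval[1] + slack)
    w = len(pattern)
    for start in range(lo, hi - w + 1):
        if match_at(pattern, residues[start : start + w]):
            return start
    return None


@dataclass(frozen=True)
class DiagnosticRule:
    """A motif plus the key residues whose presence is diagnostic."""

    motif: MotifPattern
    key_positions: tuple[tuple[int, frozenset, str], ...]  # (element index, required set, label)

    def __post_init__(self) -> None:
        for idx, allowed, _label in self.key_positions:
            if not 0 <= idx < len(self.motif):
                raise ValidationError(
                    f"rule {self.motif.name!r}: key index {idx} outside motif"
                )
            if not allowed:
                raise ValidationError(f"rule {self.motif.name!r}: empty key residue set")

    def relaxed_motif(self) -> MotifPattern:
        """The motif with key positions wildcarded — used to locate the site
        even when a key residue has diverged (e.g. FslK's GARP vs GXR(M/L))."""
        keys = {idx for idx, _, _ in self.key_positions}
        elements = tuple(
            None if i in keys else el for i, el in enumerate(self.motif.elements)
        )
        return MotifPattern(
            name=self.motif.name + "~relaxed", elements=elements, subdomain=self.motif.subdomain
        )


@dataclass
class RuleOutcome:
    rule_name: str
    subdomain_present: bool
    motif_found: bool
    match_position: int | None
    key_checks: list[tuple[str, KeyStatus]]

    def all_keys_pass(self) -> bool:
        return all(status == "pass" for _, status in self.key_checks)


@dataclass
class DiagnosticReport:
    """Per-sequence TK-activity verdict over a set of diagnostic rules."""

    seq_id: str
    outcomes: list[RuleOutcome]
    verdict: Literal["TK-like", "non-TK", "indeterminate"]

    def to_json_dict(self) -> dict:
        return {
            "schema": "kinscan-diagnostics/1",
            "seq_id": self.seq_id,
            "verdict": self.verdict,
            "rules": [
                {
                    "name": o.rule_name,
                    "subdomain_present": o.subdomain_present,
                    "motif_found": o.motif_found,
                    "match_position": o.match_position,
                    "key_checks": [{"label": lab, "status": st} for lab, st in o.key_checks],
                }
                for o in self.outcomes
            ],
        }


def default_rules() -> list[DiagnosticRule]:
    """The three TK diagnostic rules (catalytic-loop, P+1 proline, GXR(M/L))."""
    m1 = parse_pattern("DL(R/A)A(A/R)N", subdomain="VI", name="motif1")
    m2 = parse_pattern("XP(I/V)(K/R)W(T/M)APE", subdomain="VIII", name="motif2")
    m3 = parse_pattern("GXR(M/L)", subdomain="X", name="motif3")
    return [
        DiagnosticRule(
            motif=m1,
            key_positions=(
                (2, frozenset("RA"), "catalytic-loop key 1"),
                (3, frozenset("A"), "catalytic-loop key 2"),
                (4, frozenset("AR"), "catalytic-loop key 3"),
                (5, frozenset("N"), "catalytic-loop key 4"),
            ),
        ),
        DiagnosticRule(
            motif=m2,
            key_positions=((1, frozenset("P"), "substrate-recognition proline"),),
        ),
        DiagnosticRule(
            motif=m3,
            key_positions=((3, frozenset("ML"), "motif3 fourth residue M/L"),),
        ),
    ]


def _evaluate_rule(
    seq: ProteinSequence, anchors: SubdomainAnchors, rule: DiagnosticRule, slack: int
) -> RuleOutcome:
    pos = scan_window(seq, anchors, rule.motif, slack=slack)
    if pos is ABSENT:
        return RuleOutcome(
            rule_name=rule.motif.name,
            subdomain_present=False,
            motif_found=False,
            match_position=None,
            key_checks=[(label, "absent") for _, _, label in rule.key_positions],
        )
    if pos is not None:
        site, found = pos, True
    else:
        # key residue(s) may have diverged: locate via the relaxed pattern
        site = scan_window(seq, anchors, rule.relaxed_motif(), slack=slack)
        found = False
    if site is None:
        return RuleOutcome(
            rule_name=rule.motif.name,
            subdomain_present=True,
            motif_found=False,
            match_position=None,
            key_checks=[(label, "absent") for _, _, label in rule.key_positions],
        )
    checks: list[tuple[str, KeyStatus]] = []
    for idx, allowed, label in rule.key_positions:
        ch = seq.residues[site + idx]
        checks.append((label, "pass" if ch in allowed else "fail"))
    return RuleOutcome(
        rule_name=rule.motif.name,
        subdomain_present=True,
        motif_found=found,
        match_position=site,
        key_checks=checks,
    )


def diagnose_tk(
    seq: ProteinSequence,
    anchors: SubdomainAnchors,
    rules: Sequence[DiagnosticRule] | None = None,
    slack: int = 5,
) -> DiagnosticReport:
    """Apply the diagnostic rules and return the TK-activity verdict.

    Truncation takes precedence: if any required subdomain window is absent
    the verdict is ``indeterminate`` regardless of the other rules.
    """
    if rules is None:
        rules = default_rules()
    outcomes = [_evaluate_rule(seq, anchors, r, slack) for r in rules]
    if any(not o.subdomain_present for o in outcomes):
        verdict = "indeterminate"
    elif all(o.motif_found and o.all_keys_pass() for o in outcomes):
        verdict = "TK-like"
    else:
        verdict = "non-TK"
    return DiagnosticReport(seq_id=seq.id, outcomes=outcomes, verdict=verdict)


# ---------------------------------------------------------------------------
# sequence-logo column statistics

LOG2_20 = math.log2(20.0)


@dataclass
class ColumnStats:
    frequencies: np.ndarray  # length 20, sums to 1
    information_bits: float
    nongap_count: int


def column_stats(
    msa: Msa,
    pseudocount: float = 0.0,
    small_sample_correction: bool = False,
    background: np.ndarray | None = None,
) -> list[ColumnStats | None]:
    """Per-column residue frequencies and information content in bits.

    IC(c) = log2(20) - H(c) - e(c), where H is the Shannon entropy of the
    (pseudocounted) column distribution and e(c) = 19 / (2 ln2 N_c) is the
    small-sample correction; IC is clamped at 0.  All-gap columns are
    reported as ``None``.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    q = np.full(20, 1 / 20) if background is None else np.asarray(background, dtype=float)
    out: list[ColumnStats | None] = []
    for c in range(msa.ncol):
        counts = np.zeros(20)
        for _, aligned in msa.rows:
            ch = aligned[c]
            if ch != GAP and ch != "X":
                counts[AMINO_ACIDS.index(ch)] += 1
        n = int(counts.sum())
        if n == 0:
            out.append(None)
            continue
        freqs = (counts + pseudocount * q) / (n + pseudocount)
        nz = freqs[freqs > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        ic = LOG2_20 - entropy
        if small_sample_correction:
            ic -= 19.0 / (2.0 * math.log(2.0) * n)
        out.append(ColumnStats(frequencies=freqs, information_bits=max(ic, 0.0), nongap_count=n))
    return out


def write_column_stats(stats: Sequence[ColumnStats | None], path: str | Path) -> None:
    """TSV consumable by external logo renderers (column, IC, 20 frequencies)."""
    lines = ["column\tinformation_bits\tnongap_count\t" + "\t".join(AMINO_ACIDS)]
    for c, st in enumerate(stats):
        if st is None:
            lines.append(f"{c}\tNA\t0\t" + "\t".join(["NA"] * 20))
        else:
            freqs = "\t".join(f"{x:.6f}" for x in st.frequencies)
            lines.append(f"{c}\t{st.information_bits:.6f}\t{st.nongap_count}\t{freqs}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# comparative group-specific motif discovery

@dataclass
class GroupSpecificMotif:
    pattern: MotifPattern
    start_column: int
    in_group_match_fraction: float
    out_group_match_fraction: float
    specific: bool


def _window_candidate(
    msa: Msa, start: int, width: int, f_cons: float, max_set_size: int
) -> MotifPattern | None:
    """Smallest per-column residue sets covering >= f_cons of the target
    group's residues (capped at max_set_size, else wildcard)."""
    elements: list[Element] = []
    for c in range(start, start + width):
        counts: dict[str, int] = {}
        for _, aligned in msa.rows:
            ch = aligned[c]
            if ch != GAP and ch != "X":
                counts[ch] = counts.get(ch, 0) + 1
        total = sum(counts.values())
        if total == 0:
            elements.append(None)
            continue
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        cum = 0
        chosen: list[str] = []
        for ch, n in ranked:
            chosen.append(ch)
            cum += n
            if cum >= f_cons * total:
                break
        elements.append(frozenset(chosen) if len(chosen) <= max_set_size else None)
    if all(el is None for el in elements):
        return None
    try:
        return MotifPattern(name=f"win{start}+{width}", elements=tuple(elements))
    except ValidationError:  # pragma: no cover - width >= 2 enforced upstream
        return None


def _match_fraction(msa: Msa, start: int, pattern: MotifPattern) -> float:
    """Fraction of rows whose window matches; all-gap windows are excluded
    from the denominator, partially gapped windows count as non-matches."""
    w = len(pattern)
    matched = 0
    considered = 0
    for _, aligned in msa.rows:
        window = aligned[start : start + w]
        if all(ch == GAP for ch in window):
            continue
        considered += 1
        if GAP in window:
            continue
        if match_at(pattern, window):
            matched += 1
    return matched / considered if considered else 0.0


def discover_group_specific_motifs(
    msa_a: Msa,
    msa_b: Msa,
    width: int,
    f_cons: float = 0.7,
    f_in: float = 0.8,
    f_out: float = 0.2,
    max_set_size: int = 2,
) -> list[GroupSpecificMotif]:
    """Scan windows of ``width`` columns for motifs conserved in group A.

    Both alignments must share a column coordinate system (same template).
    A candidate is ``specific`` when its match fraction is >= ``f_in`` in A
    and <= ``f_out`` in B; overlapping specific windows are merged, keeping
    the longest (leftmost on ties).
    """
    if msa_a.ncol != msa_b.ncol:
        raise ValidationError("group alignments must share a column coordinate system")
    if not 2 <= width <= msa_a.ncol:
        raise ValidationError(f"window width {width} outside [2, {msa_a.ncol}]")
    found: list[GroupSpecificMotif] = []
    for start in range(msa_a.ncol - width + 1):
        pattern = _window_candidate(msa_a, start, width, f_cons, max_set_size)
        if pattern is None:
            continue
        frac_in = _match_fraction(msa_a, start, pattern)
        if frac_in < f_in:
            continue
        frac_out = _match_fraction(msa_b, start, pattern)
        sd = _subdomain_of(msa_a, start)
        pattern = MotifPattern(name=pattern.name, elements=pattern.elements, subdomain=sd)
        found.append(
            GroupSpecificMotif(
                pattern=pattern,
                start_column=start,
                in_group_match_fraction=frac_in,
                out_group_match_fraction=frac_out,
                specific=frac_in >= f_in and frac_out <= f_out,
            )
        )
    return _merge_overlapping(found)


def discover_over_widths(
    msa_a: Msa,
    msa_b: Msa,
    widths: Iterable[int] = range(4, 13),
    **kwargs,
) -> list[GroupSpecificMotif]:
    """Run discovery over a range of window widths and merge overlaps."""
    all_hits: list[GroupSpecificMotif] = []
    for w in widths:
        if 2 <= w <= msa_a.ncol:
            all_hits.extend(discover_group_specific_motifs(msa_a, msa_b, w, **kwargs))
    return _merge_overlapping(all_hits)


def _subdomain_of(msa: Msa, column: int) -> str | None:
    if not msa.subdomain_annotation:
        return None
    for sd, (s, e) in msa.subdomain_annotation.items():
        if s <= column < e:
            return sd
    return None


def _merge_overlapping(hits: list[GroupSpecificMotif]) -> list[GroupSpecificMotif]:
    """Among overlapping *specific* windows keep the longest (then leftmost,
    then highest in-group fraction); non-specific hits are kept as-is."""
    specific = [h for h in hits if h.specific]
    others = [h for h in hits if not h.specific]
    specific.sort(key=lambda h: (-len(h.pattern), h.start_column, -h.in_group_match_fraction))
    kept: list[GroupSpecificMotif] = []
    for h in specific:
        h_end = h.start_column + len(h.pattern)
        if all(
            h_end <= k.start_column or h.start_column >= k.start_column + len(k.pattern)
            for k in kept
        ):
            kept.append(h)
    merged = kept + others
    merged.sort(key=lambda h: (h.start_column, -len(h.pattern)))
    return merged


# ---------------------------------------------------------------------------
# rules config round-trip (plain-text table: name, subdomain, pattern, keys)

def read_rules(path: str | Path) -> list[DiagnosticRule]:
    """Read diagnostic rules from a TSV: name, subdomain, pattern, key_spec.

    ``key_spec`` is ``;``-separated ``index=RESIDUES`` pairs with 0-based
    element indices, e.g. ``2=RA;3=A;4=AR;5=N``.
    """
    rules: list[DiagnosticRule] = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ParseError(f"{path}: line {i + 1}: expected 4 tab-separated fields")
        name, subdomain, pattern_text, key_spec = parts
        motif = parse_pattern(pattern_text, subdomain=subdomain, name=name)
        keys = []
        for chunk in key_spec.split(";"):
            if not chunk:
                continue
            idx_text, _, residues = chunk.partition("=")
            keys.append((int(idx_text), frozenset(residues), f"{name} key@{idx_text}"))
        rules.append(DiagnosticRule(motif=motif, key_positions=tuple(keys)))
    if not rules:
        raise ValidationError(f"{path}: no rules found")
    return rules


def write_rules(rules: Sequence[DiagnosticRule], path: str | Path) -> None:
    lines = ["# name\tsubdomain\tpattern\tkeys"]
    for r in rules:
        keys = ";".join(f"{idx}={''.join(sorted(allowed))}" for idx, allowed, _ in r.key_positions)
        lines.append(f"{r.motif.name}\t{r.motif.subdomain}\t{r.motif.to_text()}\t{keys}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_reports_json(reports: Sequence[DiagnosticReport], path: str | Path) -> None:
    payload = {"schema": "kinscan-diagnostics/1", "reports": [r.to_json_dict() for r in reports]}
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")
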