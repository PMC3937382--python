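"""Best-match classification against a profile library and iterative
lineage-profile refinement.

A sequence is assigned to the group whose profile scores it highest,
provided that score reaches the cutoff; otherwise it is ``unclassified``.
``iterative_refine`` mirrors the seed-and-extend search used to delineate a
new lineage: a profile built from the seed members is added to the library,
the corpus is re-classified, newly accepted members are folded back into
the profile (aligned onto the seed template columns through their local-
alignment trace), and the loop repeats until no new member is accepted.
Acceptance is cumulative, which guarantees termination on a finite corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .errors import ValidationError
from .io_formats import Msa, ProteinSequence
from .profile_model import (
    ProfileModel,
    build_profile,
    project_to_columns,
    read_profile,
    score_only,
    write_profile,
)

UNCLASSIFIED = "unclassified"


@dataclass
class ProfileLibrary:
    """An ordered collection of uniquely named profiles.

    ``cutoff_bits`` overrides every profile's own cutoff when set.
    """

    profiles: list[ProfileModel]
    cutoff_bits: float | None = None

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValidationError("profile library must be nonempty")
        names = [p.name for p in self.profiles]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate profile names: {sorted(names)}")

    def names(self) -> list[str]:
        return [p.name for p in self.profiles]

    def cutoff_for(self, profile: ProfileModel) -> float:
        return self.cutoff_bits if self.cutoff_bits is not None else profile.cutoff_bits

    def with_profile(self, profile: ProfileModel) -> "ProfileLibrary":
        """A new library with ``profile`` appended (replacing a same-named one)."""
        kept = [p for p in self.profiles if p.name != profile.name]
        return ProfileLibrary(kept + [profile], cutoff_bits=self.cutoff_bits)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for p in self.profiles:
            write_profile(p, directory / f"{p.name}.profile")

    @classmethod
    def load(cls, directory: str | Path, cutoff_bits: float | None = None) -> "ProfileLibrary":
        paths = sorted(Path(directory).glob("*.profile"))
        return cls([read_profile(p) for p in paths], cutoff_bits=cutoff_bits)


@dataclass
class ClassificationResult:
    seq_id: str
    best_group: str  # profile name or "unclassified"
    best_score_bits: float
    runner_up_group: str | None
    margin_bits: float
    passed_cutoff: bool

    def __post_init__(self) -> None:
        if self.margin_bits < 0:
            raise ValidationError("margin_bits must be >= 0")
        if (self.best_group == UNCLASSIFIED) != (not self.passed_cutoff):
            raise ValidationError("best_group is 'unclassified' iff the cutoff was missed")


def classify_best_match(library: ProfileLibrary, seq: ProteinSequence) -> ClassificationResult:
    """Score against every profile; best match wins, subject to the cutoff.

    Ties are broken by library order (the earlier profile wins).
    """
    scores = [(p.name, score_only(p, seq)) for p in library.profiles]
    best_idx = max(range(len(scores)), key=lambda i: scores[i][1])
    # library order wins ties: max() already returns the first maximal index
    best_name, best_score = scores[best_idx]
    runner_name, runner_score = None, None
    for i, (name, sc) in enumerate(scores):
        if i == best_idx:
            continue
        if runner_score is None or sc > runner_score:
            runner_name, runner_score = name, sc
    margin = 0.0 if runner_score is None else best_score - runner_score
    passed = best_score >= library.cutoff_for(library.profiles[best_idx])
    return ClassificationResult(
        seq_id=seq.id,
        best_group=best_name if passed else UNCLASSIFIED,
        best_score_bits=best_score,
        runner_up_group=runner_name,
        margin_bits=max(margin, 0.0),
        passed_cutoff=passed,
    )


def classify_proteome(
    library: ProfileLibrary, sequences: Sequence[ProteinSequence]
) -> list[ClassificationResult]:
    """Elementwise :func:`classify_best_match`, preserving input order."""
    ids = [s.id for s in sequences]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate sequence ids: {dupes}")
    return [classify_best_match(library, s) for s in sequences]


@dataclass
class IterativeSearchResult:
    accepted_per_iteration: list[frozenset]  # cumulative id sets
    final_profile: ProfileModel
    iterations_run: int

    @property
    def accepted(self) -> frozenset:
        return self.accepted_per_iteration[-1] if self.accepted_per_iteration else frozenset()


def iterative_refine(
    library: ProfileLibrary,
    target_group: str,
    seed_hits: Msa,
    corpus: Sequence[ProteinSequence],
    max_iter: int = 5,
    pseudocount_weight: float = 1.0,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    cutoff_bits: float | None = None,
    max_gap_fraction: float | None = None,
) -> IterativeSearchResult:
    """Iteratively refine a lineage profile from seed members.

    The seed alignment's columns are the fixed template; accepted corpus
    members are mapped onto those columns via their local-alignment trace
    (no re-alignment per iteration, keeping the loop deterministic).  A
    corpus sequence is accepted when its best match is ``target_group`` at
    or above the cutoff; the accepted set is cumulative, so the loop
    reaches a fixpoint in at most ``max_iter`` iterations.
    """
    if seed_hits.nrow < 2:
        raise ValidationError("seed alignment must have at least 2 rows")
    if max_iter < 1:
        raise ValidationError("max_iter must be >= 1")
    ids = [s.id for s in corpus]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate ids in corpus")
    by_id = {s.id: s for s in corpus}
    if max_gap_fraction is not None:
        from .profile_model import trim_columns

        seed_hits = trim_columns(seed_hits, max_gap_fraction)
    cutoff = cutoff_bits if cutoff_bits is not None else 20.0
    accepted: dict[str, str] = {}  # id -> projected row
    snapshots: list[frozenset] = []
    iterations = 0
    final_profile: ProfileModel | None = None
    for _ in range(max_iter):
        iterations += 1
        rows = list(seed_hits.rows) + [(sid, accepted[sid]) for sid in sorted(accepted)]
        profile = build_profile(
            Msa(rows),
            pseudocount_weight=pseudocount_weight,
            gap_open=gap_open,
            gap_extend=gap_extend,
            cutoff_bits=cutoff,
            name=target_group,
        )
        final_profile = profile
        lib = library.with_profile(profile)
        lib = ProfileLibrary(lib.profiles, cutoff_bits=None)  # per-profile cutoffs
        new_ids: list[str] = []
        for seq in corpus:
            if seq.id in accepted:
                continue
            result = classify_best_match(lib, seq)
            if result.passed_cutoff and result.best_group == target_group:
                new_ids.append(seq.id)
        for sid in new_ids:
            accepted[sid] = project_to_columns(profile, by_id[sid])
        snapshots.append(frozenset(accepted))
        if not new_ids:
            break
    assert final_profile is not None
    return IterativeSearchResult(
        accepted_per_iteration=snapshots,
        final_profile=final_profile,
        iterations_run=iterations,
    )


def classification_table(results: Sequence[ClassificationResult], species: dict[str, str] | None = None):
    """Results as a pandas DataFrame (seq_id, species, best_group, scores)."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append(
            {
                "seq_id": r.seq_id,
                "species": (species or {}).get(r.seq_id, "unknown"),
                "best_group": r.best_group,
                "score_bits": r.best_score_bits,
                "margin_bits": r.margin_bits,
                "passed_cutoff": r.passed_cutoff,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["seq_id", "species", "best_group", "score_bits", "margin_bits", "passed_cutoff"],
    )
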