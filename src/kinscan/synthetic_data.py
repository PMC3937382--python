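"""Labeled synthetic kinase-domain benchmarks.

The generator emulates the statistical structure the analysis assumes: three
kinase groups (TK-like, TKL-like, FslK-like) built on one shared synthetic
catalytic-domain scaffold with annotated Hanks subdomains I..XI, carrying
group-diagnostic motif instances in the right subdomains; point
substitutions and geometric-length indels at configurable rates; occasional
domain truncations (emulating sequencing gaps / wrong gene models);
uniform-random non-kinase decoys; and uneven per-species counts (a few
species with many members, several with none).

The scaffold is a synthetic 290-residue kinase-like domain authored for
this package (no real proteome is bundled): its blocks mimic the canonical
subdomain landmarks (Gly-rich loop, VAIK, HRD catalytic loop, DFG, APE) so
that profile anchoring behaves like it does on real kinase domains.  Beyond
the diagnostic motif slots, each non-TK group also carries fixed lineage
"drift" substitutions, reflecting that real kinase groups are deeply
diverged families rather than point variants of one sequence; the drift
magnitudes (FslK ~15, TKL ~40 positions, outgroup ~90) set the between-
group distances that the clade analysis relies on (FslK closest to TK).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .io_formats import AMINO_ACIDS, Msa, ProteinSequence

# ---------------------------------------------------------------------------
# scaffold: (subdomain label or None, block string); motif slots are marked
# with placeholders substituted per group below.

_BLOCKS: tuple[tuple[str | None, str], ...] = (
    (None, "MGSSHSGTLE"),
    ("I", "ELRLGQGGFGEVWKATW"),      # Gly-rich loop
    (None, "RGT"),
    ("II", "DVAVKTLRPE"),            # VAIK lysine
    (None, "SAD"),
    ("III", "GMQRFRNEVAVLRKTRHELDSFEHPN"),
    (None, "NLIR"),
    ("IV", "LLGVCLDREPLYIV"),
    (None, "EPL"),
    ("V", "MIVTELMSKGSLLDYLRGDKGKSLQL"),
    (None, "HGRE"),
    ("VI", "NKIHR{M1}VLVGEN"),       # catalytic loop, motif 1 slot
    (None, "LVC"),
    ("VII", "KVADFGLARELDNDE"),      # DFG
    (None, "IED"),
    ("VIII", "SN{M2}SLAY"),          # activation segment end, motif 2 slot
    (None, "RFS"),
    ("IX", "SDVWSFGVLLWEIFTYGEKPYG"),
    (None, "GQKP"),
    ("X", "YP{SHARED}KM{M3}RPE"),    # shared CW motif + motif 3 slot
    (None, "RLD"),
    ("XI", "VYELMYQCWHEKPEDRPTFSELVESLDRM"),
    (None, "EELARIAQDVMGSPAVLDHLTKGEQSVFRAGDE"),
)

#: instance of the CW(X)6RPXF-analog motif common to TK and TKL (and kept in
#: FslK to preserve the scaffold's between-group geometry)
SHARED_MOTIF_INSTANCE = "CWSYEPSERPGF"

_GROUP_SLOTS: dict[str, dict[str, str]] = {
    # TK: all three diagnostics intact
    "TK": {"M1": "DLRAAN", "M2": "APIKWTAPE", "M3": "GARM"},
    # TKL: Ser/Thr-style catalytic loop, no substrate-recognition proline,
    # no GXR(M/L) motif
    "TKL": {"M1": "DLKPEN", "M2": "AVIKWTAPE", "M3": "GAKL"},
    # FslK: catalytic-loop keys diverged, no proline, P at motif-3 position 4
    "FslK": {"M1": "DLAPHN", "M2": "GSIKWMAPE", "M3": "GARP"},
}

#: fixed lineage drift: (constant rng seed, number of substituted positions)
_GROUP_DRIFT: dict[str, tuple[int, int]] = {
    "TK": (0, 0),
    "TKL": (20201, 40),
    "FslK": (20202, 15),
    "outgroup": (20203, 90),
}

_MOTIF_SUBDOMAIN = {"M1": "VI", "M2": "VIII", "M3": "X", "SHARED": "X"}


@dataclass(frozen=True)
class GroupTemplate:
    """A group's consensus catalytic domain with annotation and planted motifs."""

    name: str
    consensus: str
    subdomain_annotation: dict[str, tuple[int, int]]
    planted_motifs: tuple[tuple[str, str, int], ...]  # (instance, subdomain, start)

    def __post_init__(self) -> None:
        for instance, subdomain, start in self.planted_motifs:
            segment = self.consensus[start : start + len(instance)]
            if segment != instance:
                raise ValidationError(
                    f"template {self.name!r}: motif {instance!r} not at position {start}"
                )
            lo, hi = self.subdomain_annotation[subdomain]
            if not (lo <= start and start + len(instance) <= hi):
                raise ValidationError(
                    f"template {self.name!r}: motif {instance!r} outside subdomain {subdomain}"
                )

    def to_msa(self) -> Msa:
        """The template as a single-row annotated alignment."""
        return Msa([(self.name, self.consensus)], subdomain_annotation=dict(self.subdomain_annotation))


def _assemble(slots: dict[str, str]) -> tuple[str, dict[str, tuple[int, int]], list[tuple[str, str, int]]]:
    parts: list[str] = []
    annotation: dict[str, tuple[int, int]] = {}
    planted: list[tuple[str, str, int]] = []
    pos = 0
    slot_values = dict(slots, SHARED=SHARED_MOTIF_INSTANCE)
    for label, block in _BLOCKS:
        text = block
        offset = 0
        while "{" in text:
            open_i = text.index("{")
            close_i = text.index("}")
            slot = text[open_i + 1 : close_i]
            instance = slot_values[slot]
            planted.append((instance, _MOTIF_SUBDOMAIN[slot], pos + open_i))
            text = text[:open_i] + instance + text[close_i + 1 :]
            offset = close_i
        if label is not None:
            annotation[label] = (pos, pos + len(text))
        parts.append(text)
        pos += len(text)
    return "".join(parts), annotation, planted


def _protected_positions(planted: list[tuple[str, str, int]], flank: int = 5) -> set[int]:
    protected: set[int] = set()
    for instance, _sd, start in planted:
        protected.update(range(max(0, start - flank), start + len(instance) + flank))
    return protected


def _apply_drift(consensus: str, planted: list[tuple[str, str, int]], seed: int, k: int) -> str:
    """Fixed lineage substitutions at k positions outside motif slots."""
    if k == 0:
        return consensus
    rng = np.random.default_rng(seed)
    protected = _protected_positions(planted)
    candidates = [i for i in range(len(consensus)) if i not in protected]
    chosen = rng.choice(len(candidates), size=k, replace=False)
    out = list(consensus)
    for idx in sorted(int(c) for c in chosen):
        pos = candidates[idx]
        alternatives = [a for a in AMINO_ACIDS if a != out[pos]]
        out[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(out)


def _build_template(name: str, slots: dict[str, str]) -> GroupTemplate:
    consensus, annotation, planted = _assemble(slots)
    drift_seed, drift_k = _GROUP_DRIFT.get(name, (0, 0))
    consensus = _apply_drift(consensus, planted, drift_seed, drift_k)
    return GroupTemplate(
        name=name,
        consensus=consensus,
        subdomain_annotation=annotation,
        planted_motifs=tuple(planted),
    )


def default_templates() -> list[GroupTemplate]:
    """The three bundled group templates (TK, TKL, FslK) on one scaffold."""
    return [_build_template(name, slots) for name, slots in _GROUP_SLOTS.items()]


def outgroup_template() -> GroupTemplate:
    """A heavily drifted kinase-like template used to root benchmark trees."""
    return _build_template("outgroup", _GROUP_SLOTS["TKL"])


# ---------------------------------------------------------------------------
# mutation and dataset generation

def mutate_sequence(
    consensus: str,
    substitution_rate: float = 0.0,
    indel_rate: float = 0.0,
    mean_indel_length: float = 2.0,
    rng: np.random.Generator | int | None = None,
) -> str:
    """Apply independent point substitutions and geometric-length indels.

    Substituted residues are drawn uniformly from the 19 alternatives, so
    the expected mismatch fraction equals ``substitution_rate``.  Indels are
    per-position events (insertion or deletion with equal probability) with
    geometric lengths of the given mean.  Motif positions are not
    protected: diagnostics must tolerate decayed motifs.
    """
    if not 0.0 <= substitution_rate <= 1.0 or not 0.0 <= indel_rate <= 1.0:
        raise ValidationError("rates must be in [0, 1]")
    if mean_indel_length < 1.0:
        raise ValidationError("mean_indel_length must be >= 1")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out: list[str] = []
    i = 0
    n = len(consensus)
    while i < n:
        if indel_rate > 0.0 and gen.random() < indel_rate:
            length = int(gen.geometric(1.0 / mean_indel_length))
            if gen.random() < 0.5:  # insertion before position i
                out.extend(AMINO_ACIDS[int(gen.integers(20))] for _ in range(length))
            else:  # deletion of the next `length` positions
                i += length
                continue
        ch = consensus[i]
        if substitution_rate > 0.0 and gen.random() < substitution_rate:
            alternatives = [a for a in AMINO_ACIDS if a != ch]
            ch = alternatives[int(gen.integers(19))]
        out.append(ch)
        i += 1
    return "".join(out) if out else consensus[:1]


DEFAULT_SPECIES_WEIGHTS: dict[str, float] = {
    # Fig-1-like skew: two species with many members, a tail, six with none
    "sp01": 8.0, "sp02": 5.0, "sp03": 3.0, "sp04": 2.0,
    "sp05": 1.0, "sp06": 1.0, "sp07": 0.5, "sp08": 0.5,
    "sp09": 0.0, "sp10": 0.0, "sp11": 0.0, "sp12": 0.0,
    "sp13": 0.0, "sp14": 0.0,
}


@dataclass
class GeneratorConfig:
    templates: list[GroupTemplate] = field(default_factory=default_templates)
    n_per_group: int = 50
    substitution_rate: float = 0.15
    indel_rate: float = 0.01
    mean_indel_length: float = 2.0
    truncation_prob: float = 0.0
    n_decoys: int = 50
    decoy_length_range: tuple[int, int] = (80, 400)
    species_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SPECIES_WEIGHTS))
    seed: int = 42

    def __post_init__(self) -> None:
        for rate in (self.substitution_rate, self.indel_rate, self.truncation_prob):
            if not 0.0 <= rate <= 1.0:
                raise ValidationError("rates must be in [0, 1]")
        if self.n_per_group < 0 or self.n_decoys < 0:
            raise ValidationError("counts must be >= 0")
        if self.n_per_group > 0 and not self.templates:
            raise ValidationError("templates required when n_per_group > 0")
        if sum(self.species_weights.values()) <= 0:
            raise ValidationError("species weights must have positive total")


@dataclass(frozen=True)
class TruthRecord:
    group: str  # template name or "decoy"
    species: str
    truncated: bool
    motif_positions: tuple[tuple[str, str, int], ...]  # (instance, subdomain, start)


@dataclass
class LabeledDataset:
    sequences: list[ProteinSequence]
    truth: dict[str, TruthRecord]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sequences]
        if set(ids) != set(self.truth) or len(ids) != len(self.truth):
            raise ValidationError("truth table must cover every sequence id exactly once")

    def ids_of_group(self, group: str) -> list[str]:
        return [s.id for s in self.sequences if self.truth[s.id].group == group]

    def write_truth_tsv(self, path: str | Path) -> None:
        lines = ["id\tgroup\tspecies\ttruncated\tmotif_positions"]
        for s in self.sequences:
            t = self.truth[s.id]
            motifs = ";".join(f"{sd}:{start}:{inst}" for inst, sd, start in t.motif_positions)
            lines.append(f"{s.id}\t{t.group}\t{t.species}\t{int(t.truncated)}\t{motifs}")
        Path(path).write_text("\n".join(lines) + "\n")


def _pick_species(rng: np.random.Generator, weights: dict[str, float]) -> str:
    names = sorted(weights)
    w = np.array([weights[n] for n in names], dtype=float)
    return names[int(rng.choice(len(names), p=w / w.sum()))]


def generate_benchmark(config: GeneratorConfig) -> LabeledDataset:
    """Generate a labeled benchmark dataset.

    Every sequence gets its own deterministic random substream keyed by
    (group index, replicate index), so changing ``n_decoys`` or the number
    of groups never perturbs the other sequences.  Ids are assigned after a
    seeded shuffle, so they encode nothing about the ground truth.
    """
    records: list[tuple[str, str, bool, tuple]] = []  # residues, species, truncated, motifs
    groups: list[str] = []
    for gi, template in enumerate(config.templates):
        for i in range(config.n_per_group):
            rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(gi, i)))
            residues = mutate_sequence(
                template.consensus,
                config.substitution_rate,
                config.indel_rate,
                config.mean_indel_length,
                rng,
            )
            truncated = False
            if config.truncation_prob > 0.0 and rng.random() < config.truncation_prob:
                cut = int(rng.integers(1, max(2, len(residues))))
                residues = residues[:cut]
                truncated = True
            species = _pick_species(rng, config.species_weights)
            records.append((residues, species, truncated, template.planted_motifs))
            groups.append(template.name)
    for i in range(config.n_decoys):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(999, i)))
        lo, hi = config.decoy_length_range
        length = int(rng.integers(lo, hi + 1))
        residues = "".join(AMINO_ACIDS[int(c)] for c in rng.integers(0, 20, size=length))
        species = _pick_species(rng, config.species_weights)
        records.append((residues, species, False, ()))
        groups.append("decoy")
    shuffle_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(12345,)))
    order = shuffle_rng.permutation(len(records))
    width = max(4, len(str(len(records))))
    sequences: list[ProteinSequence] = []
    truth: dict[str, TruthRecord] = {}
    for new_idx, old_idx in enumerate(order):
        residues, species, truncated, motifs = records[old_idx]
        seq_id = f"seq{new_idx + 1:0{width}d}"
        sequences.append(ProteinSequence(seq_id, residues, species))
        truth[seq_id] = TruthRecord(
            group=groups[old_idx], species=species, truncated=truncated, motif_positions=motifs
        )
    return LabeledDataset(sequences=sequences, truth=truth)


# ---------------------------------------------------------------------------
# iterative-refinement study corpus

@dataclass
class RefinementCorpus:
    """A lineage-search corpus with near and remote homolog tiers.

    Built from one template by two rounds of lineage drift (0.15 each) with
    members sampled at 0.02 around each tier's template: the remote tier
    shares the intermediate tier's drift, so a profile refined with the
    near members raises remote scores above the suggested cutoff while the
    seed-only profile does not.
    """

    seed_msa: Msa
    corpus: list[ProteinSequence]
    near_ids: list[str]
    remote_ids: list[str]
    suggested_cutoff_bits: float


def make_refinement_corpus(
    template: GroupTemplate,
    seed: int = 7,
    n_near: int = 10,
    n_remote: int = 5,
    drift_rate: float = 0.15,
    within_rate: float = 0.02,
    cutoff_bits: float | None = None,
) -> RefinementCorpus:
    """Build the staged-search corpus described on :class:`RefinementCorpus`.

    When ``cutoff_bits`` is not given, the suggested detection threshold is
    placed 60 bits above the remote tier's best score against the seed-only
    profile — the precondition of a staged search (near homologs detectable
    from the seed alone, remote ones not, but within reach of a refined
    profile).  The margin sits well below both the near/remote tier gap
    (>= ~120 bits) and the score gain refinement confers on the remote tier
    (>= ~110 bits), so the staged behaviour is robust to the realization.
    """
    def stream(*key: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))

    base = template.consensus
    mid = mutate_sequence(base, drift_rate, 0.0, rng=stream(0))
    far = mutate_sequence(mid, drift_rate, 0.0, rng=stream(1))
    seed_rows = [
        (f"seed{i + 1}", mutate_sequence(base, within_rate, 0.0, rng=stream(2, i)))
        for i in range(3)
    ]
    near = [
        ProteinSequence(f"near{i + 1:02d}", mutate_sequence(mid, within_rate, 0.0, rng=stream(3, i)))
        for i in range(n_near)
    ]
    remote = [
        ProteinSequence(f"remote{i + 1:02d}", mutate_sequence(far, within_rate, 0.0, rng=stream(4, i)))
        for i in range(n_remote)
    ]
    seed_msa = Msa(seed_rows)
    if cutoff_bits is None:
        from .profile_model import build_profile, score_only

        profile = build_profile(seed_msa, name="seed")
        remote_scores = [score_only(profile, s) for s in remote]
        cutoff_bits = max(remote_scores) + 60.0
    return RefinementCorpus(
        seed_msa=seed_msa,
        corpus=near + remote,
        near_ids=[s.id for s in near],
        remote_ids=[s.id for s in remote],
        suggested_cutoff_bits=float(cutoff_bits),
    )
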