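"""End-to-end orchestration: scan -> diagnose -> tree -> report.

Stages communicate through files (FASTA/TSV/JSON/newick) so each is
independently testable and resumable.  ``simulate_workspace`` writes a
complete synthetic input set (per-species proteomes, seed alignments,
subdomain table, rules file, config) so the whole pipeline runs without any
external data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classifier import (
    ProfileLibrary,
    classification_table,
    classify_proteome,
    iterative_refine,
)
from .errors import ValidationError
from .io_formats import (
    Msa,
    ProteinSequence,
    read_aligned_fasta,
    read_fasta,
    read_subdomain_table,
    sequences_to_msa,
    write_aligned_fasta,
    write_fasta,
    write_subdomain_table,
)
from .motif_diagnostics import (
    default_rules,
    diagnose_tk,
    read_rules,
    write_reports_json,
    write_rules,
)
from .phylo_lite import benchmark_clade_report, nj_tree, pairwise_distances, write_newick
from .profile_model import (
    ProfileModel,
    anchor_subdomains,
    build_profile,
    project_to_columns,
    trim_columns,
)
from .errors import UnanchorableError
from . import synthetic_data

log = logging.getLogger("kinscan")


@dataclass
class RunConfig:
    """Paths and parameters for a pipeline run.

    All paths are interpreted relative to the config file's directory when
    loaded through :meth:`from_yaml`.
    """

    proteomes: list[str] = field(default_factory=list)
    seed_alignments: dict[str, str] = field(default_factory=dict)  # group -> aligned FASTA
    reference_group: str = "TK"
    target_group: str = "FslK"
    subdomain_table: str | None = None
    rules_file: str | None = None
    outgroup_fasta: str | None = None
    refine_seed_alignment: str | None = None  # enables iterative refinement
    refine_cutoff_bits: float | None = None
    cutoff_bits: float = 20.0
    max_gap_fraction: float = 0.5
    pseudocount_weight: float = 1.0
    gap_open: float = 11.0
    gap_extend: float = 1.0
    distance_model: str = "p-distance"
    # minimum fraction of reference columns a candidate must cover to enter
    # the tree (domain-confirmation analog: drops spurious low-coverage hits)
    min_domain_coverage: float = 0.5
    discovery_f_cons: float = 0.7
    discovery_f_in: float = 0.8
    discovery_f_out: float = 0.2
    discovery_max_set_size: int = 2
    seed: int = 42
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        config = cls(**raw)
        base = path.parent
        config.proteomes = [str(base / p) for p in config.proteomes]
        config.seed_alignments = {g: str(base / p) for g, p in config.seed_alignments.items()}
        for attr in ("subdomain_table", "rules_file", "outgroup_fasta", "refine_seed_alignment"):
            value = getattr(config, attr)
            if value is not None:
                setattr(config, attr, str(base / value))
        if not Path(config.outdir).is_absolute():
            config.outdir = str(base / config.outdir)
        return config

    def validate_paths(self) -> None:
        missing = [p for p in self.proteomes if not Path(p).exists()]
        missing += [p for p in self.seed_alignments.values() if not Path(p).exists()]
        for attr in ("subdomain_table", "rules_file", "outgroup_fasta", "refine_seed_alignment"):
            value = getattr(self, attr)
            if value is not None and not Path(value).exists():
                missing.append(value)
        if missing:
            raise ValidationError(f"missing input files: {missing}")


def _load_library(config: RunConfig) -> ProfileLibrary:
    profiles = []
    for group, path in config.seed_alignments.items():
        msa = read_aligned_fasta(path)
        msa = trim_columns(msa, config.max_gap_fraction)
        profiles.append(
            build_profile(
                msa,
                pseudocount_weight=config.pseudocount_weight,
                gap_open=config.gap_open,
                gap_extend=config.gap_extend,
                cutoff_bits=config.cutoff_bits,
                name=group,
            )
        )
    if not profiles:
        raise ValidationError("no seed alignments configured")
    return ProfileLibrary(profiles)


def _reference_profile(config: RunConfig) -> ProfileModel:
    try:
        path = config.seed_alignments[config.reference_group]
    except KeyError as exc:
        raise ValidationError(
            f"reference group {config.reference_group!r} has no seed alignment"
        ) from exc
    annotation = read_subdomain_table(config.subdomain_table) if config.subdomain_table else None
    msa = read_aligned_fasta(path, subdomain_annotation=annotation)
    msa = trim_columns(msa, config.max_gap_fraction)
    return build_profile(
        msa,
        pseudocount_weight=config.pseudocount_weight,
        gap_open=config.gap_open,
        gap_extend=config.gap_extend,
        cutoff_bits=config.cutoff_bits,
        name=config.reference_group,
    )


def _read_proteomes(config: RunConfig) -> list[ProteinSequence]:
    sequences: list[ProteinSequence] = []
    seen: set[str] = set()
    for path in config.proteomes:
        for seq in read_fasta(path):
            if seq.id in seen:
                raise ValidationError(f"duplicate sequence id {seq.id!r} across proteomes")
            seen.add(seq.id)
            if seq.species == "unknown":
                seq = ProteinSequence(seq.id, seq.residues, Path(path).stem)
            sequences.append(seq)
    return sequences


def run_scan(config: RunConfig) -> dict[str, str]:
    """Classify every proteome sequence; write classification TSV and the
    accepted-set FASTA.  Runs iterative refinement first when a lineage
    seed alignment is configured."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sequences = _read_proteomes(config)
    library = _load_library(config)
    if config.refine_seed_alignment:
        seed_msa = read_aligned_fasta(config.refine_seed_alignment)
        refinement = iterative_refine(
            library,
            config.target_group,
            seed_msa,
            sequences,
            pseudocount_weight=config.pseudocount_weight,
            gap_open=config.gap_open,
            gap_extend=config.gap_extend,
            cutoff_bits=config.refine_cutoff_bits or config.cutoff_bits,
        )
        library = library.with_profile(refinement.final_profile)
        log.info(
            "scan: refinement accepted %d ids in %d iterations",
            len(refinement.accepted),
            refinement.iterations_run,
        )
    results = classify_proteome(library, sequences)
    species = {s.id: s.species for s in sequences}
    table = classification_table(results, species)
    tsv_path = outdir / "classification.tsv"
    table.to_csv(tsv_path, sep="\t", index=False)
    accepted = [s for s, r in zip(sequences, results) if r.passed_cutoff]
    fasta_path = outdir / "accepted.fasta"
    write_fasta(accepted, fasta_path)
    log.info(
        "scan: %d sequences in, %d accepted (groups: %s)",
        len(sequences),
        len(accepted),
        ",".join(library.names()),
    )
    return {"classification": str(tsv_path), "accepted": str(fasta_path)}


def run_diagnose(config: RunConfig, accepted_fasta: str | Path) -> dict[str, str]:
    """Anchor subdomains and apply the TK diagnostic rules per sequence.

    Unanchorable or truncated sequences are reported ``indeterminate``,
    never dropped.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = _reference_profile(config)
    if not reference.subdomains:
        raise ValidationError("diagnosis requires a subdomain table for the reference alignment")
    rules = read_rules(config.rules_file) if config.rules_file else default_rules()
    sequences = read_fasta(accepted_fasta)
    reports = []
    rows = []
    for seq in sequences:
        try:
            anchors = anchor_subdomains(reference, seq)
        except UnanchorableError:
            rows.append(
                {
                    "seq_id": seq.id,
                    "verdict": "indeterminate",
                    "complete_domain": False,
                    "n_subdomains": 0,
                    **{f"{r.motif.name}_found": False for r in rules},
                }
            )
            continue
        report = diagnose_tk(seq, anchors, rules)
        reports.append(report)
        rows.append(
            {
                "seq_id": seq.id,
                "verdict": report.verdict,
                "complete_domain": anchors.complete(),
                "n_subdomains": anchors.n_present(),
                **{o.rule_name + "_found": o.motif_found for o in report.outcomes},
            }
        )
    json_path = outdir / "diagnostics.json"
    write_reports_json(reports, json_path)
    tsv_path = outdir / "diagnostics.tsv"
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    log.info("diagnose: %d sequences, %d anchorable", len(sequences), len(reports))
    return {"diagnostics": str(tsv_path), "diagnostics_json": str(json_path)}


def run_tree(
    config: RunConfig,
    accepted_fasta: str | Path,
    classification_tsv: str | Path | None = None,
) -> dict[str, str]:
    """Template-anchored alignment, trimming, distances, NJ, outgroup
    rooting, and the candidate-clade/sister-group report.

    The candidate clade is the accepted sequences classified into the
    target group (all accepted sequences when no classification table is
    given); reference seed sets for the *other* groups and the outgroup
    provide the comparative context, mirroring a lineage-placement tree.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not config.outgroup_fasta:
        raise ValidationError("tree stage requires outgroup_fasta")
    reference = _reference_profile(config)
    accepted = read_fasta(accepted_fasta)
    if classification_tsv is not None:
        cls = pd.read_csv(classification_tsv, sep="\t")
        target_ids = set(cls.loc[cls["best_group"] == config.target_group, "seq_id"])
        accepted = [s for s in accepted if s.id in target_ids]
    projected: list[tuple[str, str]] = []
    kept_candidates: list[str] = []
    for seq in accepted:
        row = project_to_columns(reference, seq)
        coverage = 1.0 - row.count("-") / len(row)
        if coverage >= config.min_domain_coverage:
            projected.append((seq.id, row))
            kept_candidates.append(seq.id)
        else:
            log.info("tree: dropping %s (domain coverage %.2f)", seq.id, coverage)
    if len(projected) < 3:
        raise ValidationError(f"tree stage needs >= 3 candidate sequences, got {len(projected)}")
    outgroup = read_fasta(config.outgroup_fasta)
    reference_groups: dict[str, list[str]] = {}
    rows: list[tuple[str, str]] = list(projected)
    taken: set[str] = {sid for sid, _ in projected}
    for seq in outgroup:
        rows.append((seq.id, project_to_columns(reference, seq)))
        taken.add(seq.id)
    for group, path in config.seed_alignments.items():
        if group == config.target_group:
            continue  # the candidate set itself represents the target lineage
        members = []
        for seq in read_aligned_fasta(path).degapped():
            if seq.id in taken:
                continue
            rows.append((seq.id, project_to_columns(reference, seq)))
            taken.add(seq.id)
            members.append(seq.id)
        reference_groups[group] = members
    msa = trim_columns(Msa(rows), config.max_gap_fraction)
    dm = pairwise_distances(msa, config.distance_model)  # type: ignore[arg-type]
    tree = nj_tree(dm)
    newick_path = outdir / "tree.nwk"
    write_newick(tree, newick_path)
    report = benchmark_clade_report(
        tree,
        candidate=kept_candidates,
        outgroup=[s.id for s in outgroup],
        reference_groups=reference_groups,
    )
    report_path = outdir / "clade_report.json"
    report_path.write_text(json.dumps(report, indent=1) + "\n")
    log.info(
        "tree: %d leaves, candidate monophyletic=%s sister=%s",
        len(msa.rows),
        report["candidate_monophyletic"],
        report["sister_matches"],
    )
    return {"tree": str(newick_path), "clade_report": str(report_path)}


def run_report(
    classification_tsv: str | Path,
    diagnostics_tsv: str | Path | None,
    truth_tsv: str | Path | None = None,
    target_group: str = "FslK",
    outdir: str | Path = "results",
) -> dict[str, str]:
    """Per-species member counts (with domain completeness) and, when the
    truth table is given, the truth-vs-predicted confusion matrix."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cls = pd.read_csv(classification_tsv, sep="\t")
    merged = cls
    if diagnostics_tsv is not None and Path(diagnostics_tsv).exists():
        diag = pd.read_csv(diagnostics_tsv, sep="\t")
        merged = cls.merge(
            diag[["seq_id", "verdict", "complete_domain"]], on="seq_id", how="left"
        )
    else:
        merged = merged.assign(verdict=pd.NA, complete_domain=pd.NA)
    report_path = outdir / "report.tsv"
    merged.to_csv(report_path, sep="\t", index=False)
    members = merged[merged["best_group"] == target_group].copy()
    members["complete"] = members["complete_domain"].eq(True)
    dist = (
        members.groupby("species")
        .agg(n_members=("seq_id", "count"), n_complete_domain=("complete", "sum"))
        .reset_index()
    )
    dist["n_truncated"] = dist["n_members"] - dist["n_complete_domain"]
    dist_path = outdir / "species_distribution.tsv"
    dist.to_csv(dist_path, sep="\t", index=False)
    outputs = {"report": str(report_path), "species_distribution": str(dist_path)}
    if truth_tsv is not None:
        truth = pd.read_csv(truth_tsv, sep="\t")
        orphans = set(truth["id"]).symmetric_difference(set(cls["seq_id"]))
        if orphans:
            raise ValidationError(f"id mismatch between truth and classification: {sorted(orphans)}")
        joined = cls.merge(truth[["id", "group"]], left_on="seq_id", right_on="id")
        confusion = pd.crosstab(joined["group"], joined["best_group"], dropna=False)
        confusion_path = outdir / "confusion.tsv"
        confusion.to_csv(confusion_path, sep="\t")
        outputs["confusion"] = str(confusion_path)
    log.info("report: %d species with members of %s", len(dist), target_group)
    return outputs


# ---------------------------------------------------------------------------
# synthetic workspace

def simulate_workspace(
    outdir: str | Path,
    seed: int = 42,
    config_overrides: dict | None = None,
    n_seed_members: int = 8,
    n_outgroup: int = 4,
) -> Path:
    """Write a complete synthetic input workspace and its config.yaml.

    Produces per-species proteome FASTA files from the default benchmark,
    seed alignments sampled around each group template (low divergence, no
    indels, hence trivially aligned), an outgroup FASTA, the scaffold's
    subdomain table, the default diagnostic rules, and the ground-truth
    table for later evaluation.
    """
    outdir = Path(outdir)
    (outdir / "proteomes").mkdir(parents=True, exist_ok=True)
    (outdir / "seeds").mkdir(exist_ok=True)
    overrides = dict(config_overrides or {})
    gen_keys = {f.name for f in dataclasses.fields(synthetic_data.GeneratorConfig)}
    gen_overrides = {k: overrides.pop(k) for k in list(overrides) if k in gen_keys}
    gen_config = synthetic_data.GeneratorConfig(seed=seed, **gen_overrides)
    dataset = synthetic_data.generate_benchmark(gen_config)
    by_species: dict[str, list[ProteinSequence]] = {}
    for seq in dataset.sequences:
        by_species.setdefault(seq.species, []).append(seq)
    proteome_paths = []
    for species in sorted(by_species):
        path = outdir / "proteomes" / f"{species}.fasta"
        write_fasta(by_species[species], path)
        proteome_paths.append(f"proteomes/{species}.fasta")
    dataset.write_truth_tsv(outdir / "truth.tsv")

    templates = {t.name: t for t in gen_config.templates}
    seed_paths: dict[str, str] = {}
    for gi, (name, template) in enumerate(sorted(templates.items())):
        members = []
        for i in range(n_seed_members):
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(555, gi, i)))
            members.append(
                ProteinSequence(
                    f"{name}_seed{i + 1}",
                    synthetic_data.mutate_sequence(template.consensus, 0.05, 0.0, rng=rng),
                )
            )
        path = outdir / "seeds" / f"{name}.afa"
        write_aligned_fasta(sequences_to_msa(members), path)
        seed_paths[name] = f"seeds/{name}.afa"
    og_template = synthetic_data.outgroup_template()
    og_members = []
    for i in range(n_outgroup):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(556, i)))
        og_members.append(
            ProteinSequence(
                f"outgroup{i + 1}",
                synthetic_data.mutate_sequence(og_template.consensus, 0.05, 0.0, rng=rng),
            )
        )
    write_fasta(og_members, outdir / "outgroup.fasta")
    any_template = next(iter(templates.values()))
    write_subdomain_table(any_template.subdomain_annotation, outdir / "subdomains.tsv")
    write_rules(default_rules(), outdir / "rules.txt")
    config = RunConfig(
        proteomes=proteome_paths,
        seed_alignments=seed_paths,
        reference_group="TK",
        target_group="FslK",
        subdomain_table="subdomains.tsv",
        rules_file="rules.txt",
        outgroup_fasta="outgroup.fasta",
        seed=seed,
        outdir="results",
        **overrides,
    )
    payload = dataclasses.asdict(config)
    (outdir / "config.yaml").write_text(yaml.safe_dump(payload, sort_keys=False))
    log.info("simulate: %d sequences across %d species -> %s", len(dataset.sequences), len(by_species), outdir)
    return outdir / "config.yaml"
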