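"""End-to-end run: FASTA -> features -> labels -> alignment -> tree.

Outputs are a pure function of (input bytes, config, seed): tables use a
fixed column order, floats are formatted, and all resampling randomness
derives from the single config seed. Every artifact lands in ``out_dir``
together with a run log recording the config.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import classify as _classify
from .alignment import ScoringScheme, center_star_msa, trim_columns
from .errors import PhyloError, PipelineStageError, SiroclassError
from .feature_detect import AnchorProfile, build_feature_vector, default_profile
from .phylo import bootstrap_support, distance_matrix, nj_tree, write_newick
from .seq_io import (
    RunConfig,
    feature_table_frame,
    read_fasta,
    write_feature_table,
)


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, exc) from exc
            return False

    return _Ctx()


def load_profile(config: RunConfig) -> AnchorProfile:
    if config.anchor_profile_path:
        return AnchorProfile.from_yaml(config.anchor_profile_path)
    return default_profile()


def classify_records(records, profile: AnchorProfile, config: RunConfig):
    """Feature vectors + labels for a list of records."""
    scheme = ScoringScheme.blosum62(config.gap_open, config.gap_extend)
    if profile.core_score_threshold != config.min_core_score:
        profile = type(profile)(
            dsr_reference=profile.dsr_reference,
            frh_reference=profile.frh_reference,
            anchor_sites=profile.anchor_sites,
            ferredoxin_motif=profile.ferredoxin_motif,
            core_score_threshold=config.min_core_score,
            version=profile.version,
        )
    fvs = [
        build_feature_vector(
            rec,
            profile,
            scheme,
            siroheme_min_anchors=config.siroheme_min_anchors,
            peripheral_min_anchors=config.peripheral_min_anchors,
        )
        for rec in records
    ]
    labels = [_classify.classify_protein(fv) for fv in fvs]
    return fvs, labels


def run_pipeline(config: RunConfig, fasta_path, out_dir) -> dict:
    """Classify, align, trim and build a supported tree; write all outputs.

    Returns a summary dict with per-label counts and output paths. Stages
    with unmet preconditions on small inputs (alignment needs >= 2
    sequences, trees need >= 3) are skipped and noted in the run log.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    notes: list[str] = []

    with _stage("read"):
        records = read_fasta(fasta_path)

    with _stage("profile"):
        profile = load_profile(config)

    with _stage("classify"):
        fvs, labels = classify_records(records, profile, config)
        write_feature_table(records, fvs, labels, out_dir / "features.tsv")
        frame = feature_table_frame(records, fvs, labels)
        frame[
            ["id", "organism", "family", "group", "subgroup", "arch_class", "sublabel", "flags"]
        ].to_csv(out_dir / "classification.tsv", sep="\t", index=False)

    scheme = ScoringScheme.blosum62(config.gap_open, config.gap_extend)
    msa = trimmed = None
    with _stage("align"):
        if len(records) >= 2:
            msa = center_star_msa(records, scheme)
            trimmed, kept = trim_columns(msa, config.max_gap_fraction)
            trimmed.write_fasta(out_dir / "alignment_trimmed.fasta")
            with open(out_dir / "kept_columns.tsv", "w") as fh:
                fh.write("new_column\told_column\n")
                for new, old in enumerate(kept, start=1):
                    fh.write(f"{new}\t{old}\n")
        else:
            notes.append("alignment skipped: fewer than 2 sequences")

    with _stage("tree"):
        if trimmed is not None and trimmed.n_rows >= 3 and trimmed.n_cols >= 1:
            try:
                tree = bootstrap_support(
                    trimmed, config.bootstrap_n, seed=config.seed, correction="p"
                )
                write_newick(tree, out_dir / "tree.nwk")
            except PhyloError as exc:
                notes.append(f"tree skipped: {exc}")
        else:
            notes.append("tree skipped: fewer than 3 sequences or empty alignment")

    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab.short()] = counts.get(lab.short(), 0) + 1
    summary = {
        "n_records": len(records),
        "counts": dict(sorted(counts.items())),
        "seed": config.seed,
        "notes": notes,
        "out_dir": str(out_dir),
    }
    with _stage("log"):
        log = {"config": config.to_dict(), **summary}
        log.pop("out_dir", None)  # keep the log a pure function of input+config
        with open(out_dir / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return summary
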