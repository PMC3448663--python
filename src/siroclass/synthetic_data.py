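"""Labeled synthetic protein families with planted or ablated signatures.

Every template starts from the packaged anchor profile's reference
sequences. Features are ablated by point substitution (Cys->Ala at cluster
anchors, Arg/Lys->Ala at sulfite-binding anchors) rather than deletion, so
anchor coordinates stay fixed — the same way natural Dsr-LP subgroups
differ from one another at single residues. Architectures are built by
concatenation: the Fsr chimera is an N-terminal half of 311 residues (two
ferredoxin-type motifs + the FrhB core), a 13-residue linker, and a
296-residue group-IIId-like Dsr half starting at position 325, for a total
of 620 residues — the domain geometry reported for the archetypal Fsr ORF.

Mutation applies independent per-site substitutions (uniform over the 19
alternative residues) at rate ``mu`` outside anchors and ``anchor_mu`` at
anchors, plus length-1..3 indels placed uniformly outside anchor +-2
neighborhoods, with anchor coordinates re-indexed after each indel. All
randomness is driven by explicit seeds; identical specs give byte-identical
FASTA output.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .feature_detect import AnchorProfile, FeatureVector, detect_ferredoxin_motifs
from .errors import SiroclassError
from .seq_io import AMINO_ACIDS, ProteinRecord

DSRLP_LABELS = tuple(g + s for g in ("I", "II", "III") for s in "abcd")
ARCH_LABELS = ("FRHB_LIKE", "FPOF_FAMILY", "FDHB_LIKE")
ALL_LABELS = DSRLP_LABELS + ("FSR",) + ARCH_LABELS + ("UNCLASSIFIED",)

# A canonical ferredoxin-type [Fe4-S4] motif block: C-x(2)-C-x(2)-C-x(3)-C.
FERREDOXIN_BLOCK = "CAACPPCAAAC"

_NO_CYS = [a for a in AMINO_ACIDS if a != "C"]


def _filler(length: int, seed: int) -> str:
    """Deterministic cysteine-free filler, so planted motifs stay unique."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(_NO_CYS, size=length))


# Fixed seeds for the non-reference segments of the templates; frozen so
# that build_template is a pure function of (label, profile).
_SEG_SEEDS = {
    "fsrn_head": 90001,
    "fsrn_sp1": 90002,
    "fsrn_sp2": 90003,
    "fsrn_tail": 90004,
    "linker": 90005,
    "frhb_flank5": 90006,
    "frhb_flank3": 90007,
    "fdhb_sp1": 90008,
    "fdhb_sp2": 90009,
    "fdhb_tail": 90010,
    "random": 90011,
}


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """One family to generate: target label, size, and noise settings."""

    label: str
    n_sequences: int = 1
    mu: float = 0.0  # per-site substitution rate outside anchors
    anchor_mu: float = 0.0  # per-site substitution rate at anchors
    indel_rate: float = 0.0  # expected indels per sequence
    seed: int = 0

    def __post_init__(self):
        if self.label not in ALL_LABELS:
            raise SiroclassError(f"unknown label {self.label!r}; choose from {ALL_LABELS}")
        if self.n_sequences < 1:
            raise SiroclassError("n_sequences must be positive")
        for name in ("mu", "anchor_mu"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise SiroclassError(f"{name} must lie in [0, 1)")
        if self.indel_rate < 0:
            raise SiroclassError("indel_rate must be >= 0")


@dataclasses.dataclass(frozen=True)
class TruthEntry:
    label: str
    feature_vector: FeatureVector
    anchor_positions: dict  # anchor name -> 1-based position in the sequence


@dataclasses.dataclass(frozen=True)
class LabeledDataset:
    records: tuple
    truth: dict  # id -> TruthEntry

    def __post_init__(self):
        ids = {r.id for r in self.records}
        if ids != set(self.truth):
            raise SiroclassError("truth must cover exactly the emitted records")


def _truth_vector(label: str) -> FeatureVector:
    def sb_for(sub: str) -> tuple:
        return {
            "a": (False, True, True, True),
            "b": (True, False, True, True),
            "c": (True, True, False, True),
            "d": (True, True, True, True),
        }[sub]

    absent_sb = (False, False, False, False)
    if label in DSRLP_LABELS:
        group, sub = label[:-1], label[-1]
        return FeatureVector(
            siroheme_site=True,
            peripheral_cluster=group in ("II", "III"),
            additional_cluster=group == "III",
            sb_present=sb_for(sub),
            frh_core=False,
            ferredoxin_n_count=0,
            ferredoxin_c_count=0,
            fusion_order_ok=False,
        )
    if label == "FSR":
        # the Dsr-side additional (**) motif sits C-terminal of the core,
        # hence the raw C-side count of 1; the linker itself is motif-free.
        return FeatureVector(
            siroheme_site=True,
            peripheral_cluster=True,
            additional_cluster=True,
            sb_present=(True, True, True, True),
            frh_core=True,
            ferredoxin_n_count=2,
            ferredoxin_c_count=1,
            fusion_order_ok=True,
        )
    if label in ARCH_LABELS:
        n = 2 if label == "FPOF_FAMILY" else 0
        c = 2 if label == "FDHB_LIKE" else 0
        return FeatureVector(
            siroheme_site=False,
            peripheral_cluster=False,
            additional_cluster=False,
            sb_present=absent_sb,
            frh_core=True,
            ferredoxin_n_count=n,
            ferredoxin_c_count=c,
            fusion_order_ok=False,
        )
    return FeatureVector(  # UNCLASSIFIED
        siroheme_site=False,
        peripheral_cluster=False,
        additional_cluster=False,
        sb_present=absent_sb,
        frh_core=False,
        ferredoxin_n_count=0,
        ferredoxin_c_count=0,
        fusion_order_ok=False,
    )


def _dsr_segment(label: str, profile: AnchorProfile) -> tuple[str, dict]:
    """Dsr-like half for a group label ('Ia'..'IIId' or 'IIId'-like for FSR).

    Returns the sequence and anchor name -> 1-based position within it.
    """
    group, sub = label[:-1], label[-1]
    seq = list(profile.dsr_reference.sequence)
    anchors: dict[str, int] = {}
    for site in profile.anchor_sites:
        anchors[site.site_id] = site.ref_position
    # additional-motif cysteines, located by scanning the reference itself
    add_window_start = profile.site("PERIPHERAL_C4").ref_position + 1
    motifs = detect_ferredoxin_motifs(
        profile.dsr_reference.sequence,
        (add_window_start, len(seq)),
        profile.ferredoxin_motif,
    )
    add_cys = [
        p
        for m in motifs
        for p in range(m[0], m[1] + 1)
        if profile.dsr_reference.sequence[p - 1] == "C"
    ]
    for k, p in enumerate(add_cys, start=1):
        anchors[f"ADDITIONAL_C{k}"] = p

    if group == "I":
        ablate = [anchors[t] for t in ("PERIPHERAL_C1", "PERIPHERAL_C2", "PERIPHERAL_C3", "PERIPHERAL_C4")]
        ablate += add_cys
    elif group == "II":
        ablate = list(add_cys)
    else:
        ablate = []
    sb_missing = {"a": "SB1", "b": "SB2", "c": "SB3", "d": None}[sub]
    if sb_missing:
        ablate.append(anchors[sb_missing])
    for p in ablate:
        seq[p - 1] = "A"
    return "".join(seq), anchors


def _offset(anchors: dict, delta: int) -> dict:
    return {k: v + delta for k, v in anchors.items()}


def _fd_anchors(prefix: str, start: int) -> dict:
    # cysteines of FERREDOXIN_BLOCK at offsets 0, 3, 6, 10
    return {f"{prefix}_C{k+1}": start + off for k, off in enumerate((0, 3, 6, 10))}


def _fsrn_half(profile: AnchorProfile) -> tuple[str, dict]:
    """The 311-residue N-half: head, two ferredoxin blocks, FrhB core, tail."""
    frh = profile.frh_reference.sequence
    head = _filler(15, _SEG_SEEDS["fsrn_head"])
    sp1 = _filler(8, _SEG_SEEDS["fsrn_sp1"])
    sp2 = _filler(10, _SEG_SEEDS["fsrn_sp2"])
    tail_len = 311 - (15 + 11 + 8 + 11 + 10 + len(frh))
    tail = _filler(tail_len, _SEG_SEEDS["fsrn_tail"])
    seq = head + FERREDOXIN_BLOCK + sp1 + FERREDOXIN_BLOCK + sp2 + frh + tail
    anchors = {}
    anchors.update(_fd_anchors("FDN1", len(head) + 1))
    anchors.update(_fd_anchors("FDN2", len(head) + 11 + len(sp1) + 1))
    assert len(seq) == 311
    return seq, anchors


def build_template(
    label: str, profile: AnchorProfile
) -> tuple[ProteinRecord, FeatureVector, dict]:
    """Deterministic template sequence + defining feature vector per label."""
    if label not in ALL_LABELS:
        raise SiroclassError(f"unknown label {label!r}")
    truth = _truth_vector(label)
    frh = profile.frh_reference.sequence
    if label in DSRLP_LABELS:
        seq, anchors = _dsr_segment(label, profile)
    elif label == "FSR":
        nhalf, n_anchors = _fsrn_half(profile)
        linker = _filler(13, _SEG_SEEDS["linker"])
        dsr, d_anchors = _dsr_segment("IIId", profile)
        seq = nhalf + linker + dsr
        anchors = dict(n_anchors)
        anchors.update(_offset(d_anchors, len(nhalf) + len(linker)))
        assert len(seq) == 620
    elif label == "FRHB_LIKE":
        f5 = _filler(12, _SEG_SEEDS["frhb_flank5"])
        f3 = _filler(12, _SEG_SEEDS["frhb_flank3"])
        seq = f5 + frh + f3
        anchors = {}
    elif label == "FPOF_FAMILY":
        seq, anchors = _fsrn_half(profile)
    elif label == "FDHB_LIKE":
        sp1 = _filler(10, _SEG_SEEDS["fdhb_sp1"])
        sp2 = _filler(8, _SEG_SEEDS["fdhb_sp2"])
        tail = _filler(15, _SEG_SEEDS["fdhb_tail"])
        seq = frh + sp1 + FERREDOXIN_BLOCK + sp2 + FERREDOXIN_BLOCK + tail
        anchors = {}
        anchors.update(_fd_anchors("FDC1", len(frh) + len(sp1) + 1))
        anchors.update(_fd_anchors("FDC2", len(frh) + len(sp1) + 11 + len(sp2) + 1))
    else:  # UNCLASSIFIED: seeded random sequence with no planted features
        seq = _filler(200, _SEG_SEEDS["random"])
        anchors = {}
    return ProteinRecord(label, seq, organism="synthetic"), truth, anchors


def mutate(
    record: ProteinRecord,
    anchor_positions: dict,
    mu: float,
    anchor_mu: float,
    indel_rate: float,
    seed: int,
) -> tuple[ProteinRecord, dict]:
    """Apply substitutions and indels; return mutated record + new anchors.

    Substitutions replace a residue with a uniform choice among the 19
    alternatives. Indels (length 1-3, insertion or deletion with equal
    probability) avoid anchor positions +-2 so planted truth stays
    well-defined; anchor coordinates are shifted accordingly.
    """
    rng = np.random.default_rng(seed)
    seq = list(record.sequence)
    anchors = dict(anchor_positions)
    anchor_set = set(anchors.values())

    thresholds = np.fromiter(
        (anchor_mu if (i + 1) in anchor_set else mu for i in range(len(seq))),
        dtype=float,
        count=len(seq),
    )
    hits = np.flatnonzero(rng.random(len(seq)) < thresholds)
    aa = list(AMINO_ACIDS)
    for i in hits:
        alternatives = [a for a in aa if a != seq[i]]
        seq[i] = alternatives[rng.integers(len(alternatives))]

    n_indels = int(rng.poisson(indel_rate))
    for _ in range(n_indels):
        length = int(rng.integers(1, 4))
        insertion = bool(rng.random() < 0.5)
        protected = set()
        for p in anchors.values():
            protected.update(range(p - 2, p + 3))
        if insertion:
            # gap slots 0..len(seq): slot k inserts between residue k and k+1;
            # forbidden when it falls inside a protected neighborhood
            slots = [
                k
                for k in range(len(seq) + 1)
                if not ({k, k + 1} & protected)
            ]
            if not slots:
                continue
            k = int(slots[rng.integers(len(slots))])
            ins = [aa[rng.integers(len(aa))] for _ in range(length)]
            seq[k:k] = ins
            anchors = {n: (p + length if p > k else p) for n, p in anchors.items()}
        else:
            starts = [
                s
                for s in range(1, len(seq) - length + 2)
                if not (set(range(s, s + length)) & protected)
            ]
            if not starts:
                continue
            s = int(starts[rng.integers(len(starts))])
            del seq[s - 1 : s - 1 + length]
            anchors = {n: (p - length if p >= s + length else p) for n, p in anchors.items()}
    return ProteinRecord(record.id, "".join(seq), record.organism), anchors


def generate_dataset(specs, profile: AnchorProfile) -> LabeledDataset:
    """Concatenate per-spec families with globally unique ``<label>_<k>`` ids."""
    specs = list(specs)
    if not specs:
        raise SiroclassError("generate_dataset needs at least one spec")
    records: list[ProteinRecord] = []
    truth: dict[str, TruthEntry] = {}
    counters: dict[str, int] = {}
    for spec in specs:
        template, truth_fv, anchors = build_template(spec.label, profile)
        for i in range(spec.n_sequences):
            k = counters.get(spec.label, 0) + 1
            counters[spec.label] = k
            rid = f"{spec.label}_{k}"
            base = ProteinRecord(rid, template.sequence, template.organism)
            mutated, new_anchors = mutate(
                base, anchors, spec.mu, spec.anchor_mu, spec.indel_rate,
                seed=np.random.SeedSequence([spec.seed, i]).generate_state(1)[0],
            )
            records.append(mutated)
            truth[rid] = TruthEntry(spec.label, truth_fv, new_anchors)
    return LabeledDataset(tuple(records), truth)


def write_truth_table(dataset: LabeledDataset, path) -> None:
    """Ground-truth contract as TSV: id, label, defining signature fields."""
    import pandas as pd

    rows = []
    for rec in dataset.records:
        entry = dataset.truth[rec.id]
        fv = entry.feature_vector
        rows.append(
            {
                "id": rec.id,
                "label": entry.label,
                "siroheme_site": int(fv.siroheme_site),
                "peripheral_cluster": int(fv.peripheral_cluster),
                "additional_cluster": int(fv.additional_cluster),
                "sb_pattern": fv.sb_pattern,
                "frh_core": int(fv.frh_core),
                "ferredoxin_n_count": fv.ferredoxin_n_count,
                "ferredoxin_c_count": fv.ferredoxin_c_count,
                "fusion_order_ok": int(fv.fusion_order_ok),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
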