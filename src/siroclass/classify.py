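"""Rule-based classification of sulfite-reductase-related proteins.

Dsr-like proteins (Dsr-LPs) fall into groups by cluster content — group I
carries only the coupled siroheme-[Fe4-S4] site, group II adds the
Dsr-type peripheral cluster (a predicted intermediate with no known
representative yet), group III adds on top of that an additional
ferredoxin-type cluster — and into subgroups a/b/c/d by which of the first
three sulfite-binding Arg/Lys residues is missing (d carries all four; the
4th is conserved across all sulfite reductases, so its absence is flagged
rather than given a subgroup). The Fsr chimera is an FrhB-like
F420-interacting region followed by a Dsr-like region; the Fsr-N family of
freestanding F420-interacting subunits is classified by where its
ferredoxin-type extensions sit relative to the FrhB core.
"""

from __future__ import annotations

import dataclasses
import warnings

from .feature_detect import FeatureVector

FAMILIES = ("DSR_LP", "FSR", "FSRN_FAMILY", "UNCLASSIFIED")
ARCH_CLASSES = ("FRHB_LIKE", "FPOF_FAMILY", "FDHB_LIKE")

# flags
MISSING_SB4 = "MISSING_SB4"
LOW_SB_COUNT = "LOW_SB_COUNT"
ANOMALOUS_ADDITIONAL = "ANOMALOUS_ADDITIONAL_WITHOUT_PERIPHERAL"
FUSION_ORDER_VIOLATION = "FUSION_ORDER_VIOLATION"


@dataclasses.dataclass(frozen=True)
class GroupLabel:
    """Classification outcome: family, Dsr-LP group/subgroup, architecture."""

    family: str
    group: str | None = None  # I / II / III, only for DSR_LP or FSR
    subgroup: str | None = None  # a / b / c / d
    arch_class: str | None = None  # only for FSRN_FAMILY or FSR
    sublabel: str | None = None
    flags: frozenset = frozenset()

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.group is not None and self.family not in ("DSR_LP", "FSR"):
            raise ValueError("group set for a non-Dsr family")
        if self.arch_class is not None and self.family not in ("FSR", "FSRN_FAMILY"):
            raise ValueError("arch_class set for a non-Fsr-N family")

    def with_flags(self, *extra: str) -> "GroupLabel":
        return dataclasses.replace(self, flags=self.flags | set(extra))

    def short(self) -> str:
        """Compact label for reports: 'IIId', 'FSR', 'FPOF_FAMILY', ..."""
        if self.family == "DSR_LP":
            return f"{self.group}{self.subgroup or ''}" if self.group else "DSR_LP"
        if self.family == "FSR":
            return "FSR"
        if self.family == "FSRN_FAMILY":
            return self.arch_class or "FSRN_FAMILY"
        return "UNCLASSIFIED"


def _subgroup(sb: tuple) -> tuple[str | None, frozenset]:
    flags: set[str] = set()
    n_present = sum(sb)
    if n_present < 3:
        flags.add(LOW_SB_COUNT)
        if not sb[3]:
            flags.add(MISSING_SB4)
        return None, frozenset(flags)
    if not sb[3]:
        return None, frozenset({MISSING_SB4})
    pattern = tuple(sb[:3])
    subgroup = {
        (True, True, True): "d",
        (False, True, True): "a",
        (True, False, True): "b",
        (True, True, False): "c",
    }[pattern]
    return subgroup, frozenset()


def classify_dsrlp(fv: FeatureVector) -> GroupLabel:
    """Assign the Dsr-LP group (I/II/III) and subgroup (a-d).

    Total on the whole feature space: every vector gets exactly one label.
    No siroheme site -> unclassified, since the coupled siroheme-[Fe4-S4]
    motif is carried by every Dsr-LP.
    """
    if not fv.siroheme_site:
        return GroupLabel("UNCLASSIFIED")
    flags: set[str] = set()
    p, a = fv.peripheral_cluster, fv.additional_cluster
    if p and a:
        group = "III"
    elif p:
        group = "II"
    elif a:
        group = "I"
        flags.add(ANOMALOUS_ADDITIONAL)
    else:
        group = "I"
    subgroup, sb_flags = _subgroup(fv.sb_present)
    return GroupLabel("DSR_LP", group=group, subgroup=subgroup, flags=frozenset(flags) | sb_flags)


def classify_fsrn(fv: FeatureVector) -> GroupLabel:
    """Assign the Fsr-N-family architecture class from core + extensions.

    A bare FrhB core is FrhB-like; a core with >=2 ferredoxin-type motifs
    N-terminal of it belongs to the FpoF family (which covers the
    freestanding Fsr-N, FpoF/FqoF, FGltS(I)-alpha and aFsr-beta
    architectures); >=2 motifs C-terminal of it is FdhB-like (FdhB,
    FGltS(II)-alpha). Anything else is recorded as unclassified with the
    observed counts in a flag.
    """
    if not fv.frh_core:
        return GroupLabel("UNCLASSIFIED")
    n, c = fv.ferredoxin_n_count, fv.ferredoxin_c_count
    if n == 0 and c == 0:
        return GroupLabel("FSRN_FAMILY", arch_class="FRHB_LIKE")
    if n >= 2 and c == 0:
        return GroupLabel("FSRN_FAMILY", arch_class="FPOF_FAMILY")
    if c >= 2 and n == 0:
        return GroupLabel("FSRN_FAMILY", arch_class="FDHB_LIKE")
    return GroupLabel("UNCLASSIFIED", flags=frozenset({f"FERREDOXIN_COUNTS_N{n}_C{c}"}))


def classify_protein(fv: FeatureVector) -> GroupLabel:
    """Full decision: Fsr chimera, Dsr-LP, Fsr-N family, or unclassified.

    A protein carrying both an FrhB core and a siroheme site in the
    fused N->C order (core before the Dsr-like region) is an Fsr: its
    Dsr-LP group/subgroup is computed from the C-terminal features and its
    architecture class from the N-terminal features, counting only
    ferredoxin motifs between core and siroheme region as C-terminal core
    extensions (the inter-domain linker), so the Dsr-side additional
    cluster is not mistaken for an Fsr-N extension. A core + siroheme
    protein in the reverse order is left unclassified with a flag: only the
    Fsr-N-then-Fsr-C architecture is defined.
    """
    if fv.frh_core and fv.siroheme_site:
        if not fv.fusion_order_ok:
            return GroupLabel("UNCLASSIFIED", flags=frozenset({FUSION_ORDER_VIOLATION}))
        dsr = classify_dsrlp(fv)
        arch_fv = dataclasses.replace(fv, ferredoxin_c_count=fv.ferredoxin_linker_count)
        arch = classify_fsrn(arch_fv)
        return GroupLabel(
            "FSR",
            group=dsr.group,
            subgroup=dsr.subgroup,
            arch_class=arch.arch_class,
            flags=dsr.flags | arch.flags,
        )
    if fv.siroheme_site:
        return classify_dsrlp(fv)
    if fv.frh_core:
        return classify_fsrn(fv)
    return GroupLabel("UNCLASSIFIED")


# genomic-context tag -> (applicable arch class, sublabel)
CONTEXT_SUBLABELS = {
    "glutamate_synthase_adjacent": {
        "FPOF_FAMILY": "FGltS(I)-alpha",
        "FDHB_LIKE": "FGltS(II)-alpha",
    },
    "sulfite_reductase_adjacent": {
        "FPOF_FAMILY": "aFsr-beta",
    },
}


def apply_context_labels(
    labels: dict[str, GroupLabel], context_table: dict[str, str]
) -> dict[str, GroupLabel]:
    """Refine Fsr-N-family labels using per-ORF genomic-context tags.

    An FpoF-family protein adjacent to a glutamate synthase subunit gains
    the FGltS(I)-alpha sublabel, one adjacent to an assimilatory sulfite
    reductase is the aFsr-beta subunit, and an FdhB-like protein next to a
    glutamate synthase is FGltS(II)-alpha. Ids without context rows are
    unchanged; unknown tags warn but do not fail.
    """
    refined = dict(labels)
    for pid, tag in context_table.items():
        if pid not in refined:
            continue
        if tag not in CONTEXT_SUBLABELS:
            warnings.warn(f"unknown context tag {tag!r} for id {pid!r}", stacklevel=2)
            continue
        label = refined[pid]
        if label.arch_class in CONTEXT_SUBLABELS[tag]:
            refined[pid] = dataclasses.replace(
                label, sublabel=CONTEXT_SUBLABELS[tag][label.arch_class]
            )
    return refined


def matches_truth(label: GroupLabel, truth: str) -> bool:
    """Does a classifier output agree with a generator truth label?"""
    if truth in ("FRHB_LIKE", "FPOF_FAMILY", "FDHB_LIKE"):
        return label.family == "FSRN_FAMILY" and label.arch_class == truth
    if truth == "FSR":
        return label.family == "FSR"
    if truth == "UNCLASSIFIED":
        return label.family == "UNCLASSIFIED"
    # Dsr-LP labels like 'Ia', 'IIId'
    group, subgroup = truth[:-1], truth[-1]
    return (
        label.family == "DSR_LP" and label.group == group and label.subgroup == subgroup
    )
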