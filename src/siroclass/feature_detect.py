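"""Locate sulfite-reductase sequence signatures on a query protein.

The signatures are the ones that define the Dsr-like protein (Dsr-LP)
family and the Fsr-N family of F420-interacting subunits:

* the four conserved cysteines assembling the coupled siroheme-[Fe4-S4]
  catalytic site (the defining feature of every siroheme sulfite
  reductase),
* the four cysteines of the Dsr-type peripheral [Fe4-S4] cluster (``*``),
* an additional ferredoxin-type [Fe4-S4] Cys motif (``**``) between the
  peripheral block and the C-terminus, absent from DsrA/B,
* the four sulfite-binding Arg/Lys positions SB1..SB4, numbered from the
  N-terminus,
* an FrhB-like core (the minimal F420-interacting unit) plus
  ferredoxin-type extensions N- or C-terminal of it.

Anchor positions are defined on a packaged reference sequence and mapped
onto queries through a free-end-gap affine alignment, so insertions and
deletions in the query shift but do not lose the anchors. An anchor is
"occupied" only when the query residue aligned to it is in the site's
allowed set; a gapped column counts as unoccupied (absence of evidence at
the anchor).
"""

from __future__ import annotations

import dataclasses
import re
from importlib import resources
from pathlib import Path

import yaml

from .alignment import PairAlignment, ScoringScheme, global_align
from .errors import SiroclassError
from .seq_io import ProteinRecord

SIROHEME_TAGS = ("SIROHEME_C1", "SIROHEME_C2", "SIROHEME_C3", "SIROHEME_C4")
PERIPHERAL_TAGS = ("PERIPHERAL_C1", "PERIPHERAL_C2", "PERIPHERAL_C3", "PERIPHERAL_C4")
SB_TAGS = ("SB1", "SB2", "SB3", "SB4")


@dataclasses.dataclass(frozen=True)
class AnchorSite:
    """One reference position that must carry a specific residue class."""

    site_id: str
    feature_tag: str
    ref_position: int  # 1-based into the Dsr-like reference
    allowed_residues: frozenset

    def __post_init__(self):
        if not self.allowed_residues:
            raise SiroclassError(f"site {self.site_id}: empty allowed-residue set")


@dataclasses.dataclass(frozen=True)
class FerredoxinPattern:
    """Cys spacing of a ferredoxin-type [Fe4-S4] motif: C-x(a)-C-x(b)-C-x(c)-C."""

    gap1: tuple = (2, 2)
    gap2: tuple = (2, 2)
    gap3: tuple = (3, 3)

    def regex(self) -> re.Pattern:
        g = lambda lo_hi: f".{{{lo_hi[0]},{lo_hi[1]}}}?"
        return re.compile(f"C{g(self.gap1)}C{g(self.gap2)}C{g(self.gap3)}C")


@dataclasses.dataclass(frozen=True)
class AnchorProfile:
    """Packaged references + anchor sites defining 'signature present'."""

    dsr_reference: ProteinRecord
    frh_reference: ProteinRecord
    anchor_sites: tuple
    ferredoxin_motif: FerredoxinPattern = FerredoxinPattern()
    core_score_threshold: float = 0.5
    version: int = 1

    def __post_init__(self):
        n = len(self.dsr_reference.sequence)
        tags = [s.feature_tag for s in self.anchor_sites]
        for family in (SIROHEME_TAGS, PERIPHERAL_TAGS, SB_TAGS):
            missing = [t for t in family if t not in tags]
            if missing:
                raise SiroclassError(f"anchor profile missing sites: {missing}")
        for site in self.anchor_sites:
            if not (1 <= site.ref_position <= n):
                raise SiroclassError(
                    f"site {site.site_id}: ref_position {site.ref_position} "
                    f"outside reference (length {n})"
                )
        sb = [self.site(t).ref_position for t in SB_TAGS]
        if sorted(sb) != sb or len(set(sb)) != 4:
            raise SiroclassError("SB sites must be strictly ordered SB1<SB2<SB3<SB4")

    def site(self, tag: str) -> AnchorSite:
        for s in self.anchor_sites:
            if s.feature_tag == tag:
                return s
        raise KeyError(tag)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnchorProfile":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        sites = tuple(
            AnchorSite(
                site_id=d["site_id"],
                feature_tag=d["feature_tag"],
                ref_position=int(d["ref_position"]),
                allowed_residues=frozenset(str(d["allowed_residues"])),
            )
            for d in data["anchor_sites"]
        )
        fm = data.get("ferredoxin_motif", {})
        pattern = FerredoxinPattern(
            gap1=tuple(fm.get("gap1", (2, 2))),
            gap2=tuple(fm.get("gap2", (2, 2))),
            gap3=tuple(fm.get("gap3", (3, 3))),
        )
        mk = lambda d: ProteinRecord(d["id"], d["sequence"], d.get("organism", ""))
        return cls(
            dsr_reference=mk(data["dsr_reference"]),
            frh_reference=mk(data["frh_reference"]),
            anchor_sites=sites,
            ferredoxin_motif=pattern,
            core_score_threshold=float(data.get("core_score_threshold", 0.5)),
            version=int(data.get("version", 1)),
        )


def default_profile() -> AnchorProfile:
    """The curated synthetic anchor profile shipped with the package."""
    ref = resources.files("siroclass").joinpath("data/anchor_profile.yaml")
    with resources.as_file(ref) as path:
        return AnchorProfile.from_yaml(path)


@dataclasses.dataclass(frozen=True)
class SiteCall:
    """Occupancy of one anchor site on a query."""

    site_id: str
    query_position: int | None  # 1-based; None when gapped
    residue: str | None
    occupied: bool


def map_anchor_sites(
    query: ProteinRecord,
    profile: AnchorProfile,
    scheme: ScoringScheme,
    alignment: PairAlignment | None = None,
) -> dict[str, SiteCall]:
    """Map every anchor site onto ``query`` via the Dsr-like reference.

    A site is occupied iff the query residue aligned to its reference
    position is in the site's allowed set. An all-gapped result is legal.
    """
    if alignment is None:
        alignment = global_align(profile.dsr_reference, query, scheme, free_end_gaps=True)
    calls = {}
    for site in profile.anchor_sites:
        qpos = alignment.query_position(site.ref_position)
        if qpos is None:
            calls[site.site_id] = SiteCall(site.site_id, None, None, False)
        else:
            residue = query.sequence[qpos - 1]
            calls[site.site_id] = SiteCall(
                site.site_id, qpos, residue, residue in site.allowed_residues
            )
    return calls


def detect_ferredoxin_motifs(
    sequence: str,
    window: tuple[int, int] | None = None,
    pattern: FerredoxinPattern = FerredoxinPattern(),
) -> list[tuple[int, int]]:
    """Non-overlapping, left-greedy Cys-spacing matches inside ``window``.

    ``window`` is a 1-based inclusive interval (default: whole sequence);
    returned intervals are 1-based inclusive and lie fully inside it.
    """
    if window is None:
        window = (1, len(sequence))
    lo, hi = window
    if not (1 <= lo and hi <= len(sequence)):
        raise SiroclassError(f"window {window} outside sequence of length {len(sequence)}")
    if lo > hi:
        return []
    region = sequence[lo - 1 : hi]
    return [
        (m.start() + lo, m.end() + lo - 1) for m in pattern.regex().finditer(region)
    ]


@dataclasses.dataclass(frozen=True)
class CoreHit:
    present: bool
    interval: tuple[int, int] | None  # 1-based inclusive query span
    score: float  # normalized to the reference self-score


def detect_frh_core(
    query: ProteinRecord, profile: AnchorProfile, scheme: ScoringScheme
) -> CoreHit:
    """Fit the FrhB-core reference into the query and score the fit.

    The fit score is normalized by the reference self-alignment score, so
    1.0 means an exact core and values near or below 0 mean no credible
    core. Present iff normalized score >= the profile threshold.
    """
    ref = profile.frh_reference
    self_score = global_align(ref, ref, scheme, free_end_gaps=True).score
    aln = global_align(ref, query, scheme, free_end_gaps=True)
    norm = aln.score / self_score if self_score > 0 else 0.0
    qpos = [p for p in aln.ref_to_query if p is not None]
    interval = (min(qpos), max(qpos)) if qpos else None
    present = norm >= profile.core_score_threshold and interval is not None
    return CoreHit(present, interval if present else interval, float(norm))


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    """Per-protein summary of every signature the classifier consumes.

    ``sb_present`` and the cluster bits are read off the anchor mapping
    only when the siroheme site itself is present: without the family's
    universal feature the Dsr-side mapping carries no evidence, so the
    remaining Dsr-side features are reported absent rather than read off a
    non-credible alignment. Ferredoxin extension counts are relative to a
    detected FrhB core (0 when there is none): ``ferredoxin_n_count``
    counts motifs strictly N-terminal of the core, ``ferredoxin_c_count``
    strictly C-terminal, and ``ferredoxin_linker_count`` only those between
    the core end and the first siroheme anchor (the chimera linker window).
    """

    siroheme_site: bool
    peripheral_cluster: bool
    additional_cluster: bool
    sb_present: tuple  # 4 bools for SB1..SB4
    frh_core: bool
    ferredoxin_n_count: int
    ferredoxin_c_count: int
    fusion_order_ok: bool
    frh_core_interval: tuple | None = None
    frh_core_score: float = 0.0
    siroheme_start: int | None = None  # query position of the first siroheme anchor
    ferredoxin_linker_count: int = 0

    @property
    def sb_pattern(self) -> str:
        return "".join("1" if b else "0" for b in self.sb_present)

    def signature(self) -> tuple:
        """The label-defining fields, for truth-table comparisons."""
        return (
            self.siroheme_site,
            self.peripheral_cluster,
            self.additional_cluster,
            self.sb_pattern,
            self.frh_core,
            self.ferredoxin_n_count,
            self.ferredoxin_c_count,
            self.fusion_order_ok,
        )


def _last_mapped_at_or_before(alignment: PairAlignment, ref_position: int) -> int | None:
    for p in range(ref_position, 0, -1):
        q = alignment.query_position(p)
        if q is not None:
            return q
    return None


def build_feature_vector(
    query: ProteinRecord,
    profile: AnchorProfile,
    scheme: ScoringScheme,
    siroheme_min_anchors: int = 4,
    peripheral_min_anchors: int = 4,
) -> FeatureVector:
    """Run every detector on ``query`` and assemble a :class:`FeatureVector`.

    The additional (``**``) cluster is searched between the peripheral
    anchor block and the C-terminus (excluding the peripheral anchors
    themselves), mirroring where that extra ferredoxin-type element sits in
    group III Dsr-LPs.
    """
    L = len(query.sequence)
    pattern = profile.ferredoxin_motif
    core = detect_frh_core(query, profile, scheme)

    dsr_aln = global_align(profile.dsr_reference, query, scheme, free_end_gaps=True)
    calls = map_anchor_sites(query, profile, scheme, alignment=dsr_aln)

    sir_occ = [calls[t].occupied for t in SIROHEME_TAGS]
    siroheme = sum(sir_occ) >= siroheme_min_anchors
    if siroheme:
        peripheral = (
            sum(calls[t].occupied for t in PERIPHERAL_TAGS) >= peripheral_min_anchors
        )
        sb = tuple(calls[t].occupied for t in SB_TAGS)
        last_peripheral_ref = profile.site("PERIPHERAL_C4").ref_position
        win_start = _last_mapped_at_or_before(dsr_aln, last_peripheral_ref)
        if win_start is not None and win_start < L:
            additional = (
                len(detect_ferredoxin_motifs(query.sequence, (win_start + 1, L), pattern))
                >= 1
            )
        else:
            additional = False
        sir_pos = [calls[t].query_position for t in SIROHEME_TAGS]
        siroheme_start = min(p for p in sir_pos if p is not None)
    else:
        peripheral = False
        additional = False
        sb = (False, False, False, False)
        siroheme_start = None

    n_count = c_count = linker_count = 0
    if core.present and core.interval is not None:
        c_start, c_end = core.interval
        if c_start > 1:
            n_count = len(
                detect_ferredoxin_motifs(query.sequence, (1, c_start - 1), pattern)
            )
        if c_end < L:
            c_count = len(
                detect_ferredoxin_motifs(query.sequence, (c_end + 1, L), pattern)
            )
        if siroheme_start is not None and c_end + 1 <= siroheme_start - 1:
            linker_count = len(
                detect_ferredoxin_motifs(
                    query.sequence, (c_end + 1, siroheme_start - 1), pattern
                )
            )

    fusion_ok = bool(
        core.present
        and siroheme
        and core.interval is not None
        and siroheme_start is not None
        and core.interval[1] < siroheme_start
    )
    return FeatureVector(
        siroheme_site=siroheme,
        peripheral_cluster=peripheral,
        additional_cluster=additional,
        sb_present=sb,
        frh_core=core.present,
        ferredoxin_n_count=n_count,
        ferredoxin_c_count=c_count,
        fusion_order_ok=fusion_ok,
        frh_core_interval=core.interval if core.present else None,
        frh_core_score=core.score,
        siroheme_start=siroheme_start,
        ferredoxin_linker_count=linker_count,
    )
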