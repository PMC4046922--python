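"""Authentication engine for cloned ancient-DNA amplifications.

Ancient mtDNA typing by PCR + bacterial cloning yields, per amplicon,
10-15 clone sequences that mix the endogenous template with post-mortem
miscoding lesions (cytosine deamination seen as C->T/G->A), sporadic
polymerase error, contaminant molecules from sample handlers, and
carry-over products from other samples processed in the same batch.

This module classifies clone origins, calls per-amplicon majority
consensus, promotes variants to a sample-level consensus only when they
reproduce across independent amplifications, types and counts miscoding
lesions, and keeps the screening/recovery bookkeeping.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .core import (
    Haplotype,
    ReferenceSegment,
    Variant,
    Window,
    is_transition,
    trim_to_window,
)
from .reference import Amplicon, get_amplicon

logger = logging.getLogger(__name__)

ENDOGENOUS = "endogenous"
STAFF_CONTAMINANT = "staff_contaminant"
CARRY_OVER = "carry_over"
UNCLASSIFIED = "unclassified"

CONTAMINANT_LABELS = frozenset({STAFF_CONTAMINANT, CARRY_OVER})

TYPE1 = "type1"  # A->G / T->C
TYPE2 = "type2"  # C->T / G->A (deamination-driven)
OTHER = "other"

VALIDATED = "validated"
PROVISIONAL = "provisional"
DISCARDED = "discarded"


class NoEndogenousSignalError(ValueError):
    """All clones of an amplicon were labelled contaminant."""


@dataclass
class CloneRead:
    """One sequenced clone of one amplicon."""

    clone_id: str
    sample_id: str
    extraction_id: str
    pcr_id: str
    fragment_id: int
    haplotype: Haplotype
    origin_label: str = UNCLASSIFIED

    def __post_init__(self) -> None:
        get_amplicon(self.fragment_id)  # must be registered


@dataclass
class CloneSet:
    """All clones of one (sample, extraction, pcr, fragment) amplification."""

    clones: list[CloneRead]
    batch_id: str = "batch-1"

    def __post_init__(self) -> None:
        if not self.clones:
            raise ValueError("empty CloneSet")
        if len(self.clones) > 50:
            raise ValueError(f"{len(self.clones)} clones exceeds the 1-50 bound")
        keys = {
            (c.sample_id, c.extraction_id, c.pcr_id, c.fragment_id)
            for c in self.clones
        }
        if len(keys) != 1:
            raise ValueError(f"clones mix provenance keys: {sorted(keys)}")

    @property
    def sample_id(self) -> str:
        return self.clones[0].sample_id

    @property
    def extraction_id(self) -> str:
        return self.clones[0].extraction_id

    @property
    def pcr_id(self) -> str:
        return self.clones[0].pcr_id

    @property
    def fragment_id(self) -> int:
        return self.clones[0].fragment_id

    @property
    def amplicon(self) -> Amplicon:
        return get_amplicon(self.fragment_id)

    def non_contaminant(self) -> list[CloneRead]:
        return [c for c in self.clones if c.origin_label not in CONTAMINANT_LABELS]


@dataclass(frozen=True)
class LesionRecord:
    """A clone-private substitution typed against the amplicon consensus."""

    clone_id: str
    position: int
    from_base: str
    to_base: str
    lesion_type: str


@dataclass
class StaffPanel:
    """HVS1 motifs of every person who handled samples or reagents."""

    members: list[tuple[str, Haplotype]] = field(default_factory=list)

    def motifs(self) -> list[tuple[str, Haplotype]]:
        return list(self.members)


@dataclass
class ConsensusProfile:
    """A skeleton's reproducibility-validated haplotype and SNP typings."""

    sample_id: str
    haplotype: Haplotype
    support: dict[Variant, list[tuple[str, str]]] = field(default_factory=dict)
    snp_typings: dict[int, tuple[str, bool]] = field(default_factory=dict)
    lesion_rate: float = 0.0
    status: str = PROVISIONAL
    notes: list[str] = field(default_factory=list)

    @property
    def validated(self) -> bool:
        return self.status == VALIDATED


@dataclass(frozen=True)
class SNPObservation:
    """One raw coding-region SNP typing with extract provenance."""

    position: int
    base: str
    extraction_id: str


def lesion_type(from_base: str, to_base: str) -> str:
    """Type a substitution: type1 = A->G/T->C, type2 = C->T/G->A, else other."""
    if (from_base, to_base) in (("A", "G"), ("T", "C")):
        return TYPE1
    if (from_base, to_base) in (("C", "T"), ("G", "A")):
        return TYPE2
    return OTHER


def _consensus_base(consensus: Haplotype, ref: ReferenceSegment, position: int) -> str:
    derived = consensus.base_at(position)
    return derived if derived is not None else ref.base(position)


def _clone_base(clone: Haplotype, ref: ReferenceSegment, position: int) -> str:
    derived = clone.base_at(position)
    return derived if derived is not None else ref.base(position)


def _differences(
    a: Haplotype, b: Haplotype, ref: ReferenceSegment, window: Window
) -> list[int]:
    """Positions (in window, outside poly-C) where two haplotypes differ."""
    positions = {v.position for v in a.variants} | {v.position for v in b.variants}
    return sorted(
        p
        for p in positions
        if p in window
        and not ref.is_excluded(p)
        and _clone_base(a, ref, p) != _clone_base(b, ref, p)
    )


def _same_motif(a: Haplotype, b: Haplotype, ref: ReferenceSegment, window: Window) -> bool:
    return not _differences(a, b, ref, window)


def per_amplicon_consensus(
    cs: CloneSet,
    ref: ReferenceSegment,
    ignore_contaminants: bool = True,
) -> tuple[Haplotype, dict[int, int], list[int]]:
    """Per-position majority consensus of an amplicon's clones.

    Returns (consensus haplotype, per-variant-position support count,
    ambiguous positions).  Majority ties are resolved to the reference
    base and flagged ambiguous — conservative toward rCRS, in the same
    spirit as requiring replication before accepting a variant.
    """
    clones = cs.non_contaminant() if ignore_contaminants else list(cs.clones)
    if not clones:
        raise NoEndogenousSignalError(
            f"amplicon {cs.sample_id}/{cs.extraction_id}/{cs.pcr_id}/f{cs.fragment_id}: "
            "all clones labelled contaminant"
        )
    window = cs.amplicon.window
    candidate_positions = sorted(
        {
            v.position
            for c in clones
            for v in c.haplotype.variants
            if v.position in window and not ref.is_excluded(v.position)
        }
    )
    variants: list[Variant] = []
    support: dict[int, int] = {}
    ambiguous: list[int] = []
    n = len(clones)
    for position in candidate_positions:
        counts = Counter(_clone_base(c.haplotype, ref, position) for c in clones)
        top_count = max(counts.values())
        winners = [b for b, k in counts.items() if k == top_count]
        ref_base = ref.base(position)
        if len(winners) > 1:
            ambiguous.append(position)
            base = ref_base if ref_base in winners else sorted(winners)[0]
        else:
            base = winners[0]
        if base != ref_base:
            variants.append(Variant(position, base))
            support[position] = counts[base]
    return Haplotype(frozenset(variants), window), support, ambiguous


def label_clone_origins(
    cs: CloneSet,
    staff: StaffPanel | None,
    batch_neighbors: Sequence[tuple[str, Haplotype]] = (),
    ref: ReferenceSegment | None = None,
) -> CloneSet:
    """Assign an origin label to every clone of an amplicon.

    A clone that deviates from the amplicon majority is a staff
    contaminant if it reproduces a handler's motif, a carry-over if it
    reproduces the motif of a *different* sample from the same batch,
    endogenous if its deviations are all damage-typed substitutions
    (type 1 or type 2), and unclassified otherwise.  ``batch_neighbors``
    are (sample_id, consensus motif) pairs for other samples in
    ``cs.batch_id``; callers are responsible for restricting them to the
    batch.
    """
    if ref is None:
        raise ValueError("a reference segment is required to compare clones")
    window = cs.amplicon.window
    majority, _, _ = per_amplicon_consensus(cs, ref, ignore_contaminants=False)

    staff_motifs: list[tuple[str, Haplotype]] = []
    if staff is None or not staff.members:
        logger.warning(
            "staff panel empty: staff-contamination check skipped for %s",
            cs.sample_id,
        )
    else:
        staff_motifs = [(pid, trim_to_window(h, window)) for pid, h in staff.members]

    neighbor_motifs = [
        (sid, trim_to_window(h, window))
        for sid, h in batch_neighbors
        if sid != cs.sample_id
    ]

    for clone in cs.clones:
        clone_h = clone.haplotype
        matches_majority = _same_motif(clone_h, majority, ref, window)
        if matches_majority:
            clone.origin_label = ENDOGENOUS
            continue
        if any(_same_motif(clone_h, m, ref, window) for _, m in staff_motifs):
            clone.origin_label = STAFF_CONTAMINANT
            continue
        if any(_same_motif(clone_h, m, ref, window) for _, m in neighbor_motifs):
            clone.origin_label = CARRY_OVER
            continue
        diffs = _differences(clone_h, majority, ref, window)
        typed = []
        for position in diffs:
            a = _consensus_base(majority, ref, position)
            b = _clone_base(clone_h, ref, position)
            if b == "d" or a == "d":
                typed.append(OTHER)
            else:
                typed.append(lesion_type(a, b))
        if typed and all(t in (TYPE1, TYPE2) for t in typed):
            clone.origin_label = ENDOGENOUS
        else:
            clone.origin_label = UNCLASSIFIED
    return cs


def classify_lesions(
    cs: CloneSet,
    consensus: Haplotype,
    ref: ReferenceSegment,
) -> list[LesionRecord]:
    """Record every clone-vs-consensus substitution as a typed lesion.

    Primer-annealing and poly-C positions never yield records;
    contaminant-labelled clones are excluded.
    """
    records: list[LesionRecord] = []
    scored = set(cs.amplicon.scored_positions(ref))
    for clone in cs.non_contaminant():
        for position in _differences(clone.haplotype, consensus, ref, cs.amplicon.window):
            if position not in scored:
                continue
            a = _consensus_base(consensus, ref, position)
            b = _clone_base(clone.haplotype, ref, position)
            if a == "d" or b == "d":
                kind = OTHER
            else:
                kind = lesion_type(a, b)
            records.append(LesionRecord(clone.clone_id, position, a, b, kind))
    return records


def lesion_rate(
    amplicons: Sequence[CloneSet],
    records: Sequence[LesionRecord],
    ref: ReferenceSegment,
    method: str = "pooled",
) -> float:
    """Miscoding-lesion rate per clone per nucleotide for one sample.

    ``pooled`` (default) divides the total lesion count by the summed
    denominator  sum_amplicons(n_clones x n_scored_bases)  — the units
    "per clone and nucleotide", weighted by how much was sequenced.
    ``per_amplicon_mean`` averages per-amplification rates instead.
    Scored bases exclude primer-annealing sites and the poly-C tract;
    contaminant-labelled clones count toward neither numerator nor
    denominator.
    """
    if method not in ("pooled", "per_amplicon_mean"):
        raise ValueError(f"unknown method {method!r}")
    by_amplicon: dict[tuple, int] = defaultdict(int)
    clone_owner = {
        c.clone_id: (cs.sample_id, cs.extraction_id, cs.pcr_id, cs.fragment_id)
        for cs in amplicons
        for c in cs.clones
    }
    for record in records:
        by_amplicon[clone_owner[record.clone_id]] += 1

    rates = []
    numerator = 0
    denominator = 0
    for cs in amplicons:
        key = (cs.sample_id, cs.extraction_id, cs.pcr_id, cs.fragment_id)
        n_clones = len(cs.non_contaminant())
        n_bases = len(cs.amplicon.scored_positions(ref))
        denom = n_clones * n_bases
        if denom == 0:
            continue
        numerator += by_amplicon[key]
        denominator += denom
        rates.append(by_amplicon[key] / denom)
    if denominator == 0:
        raise ValueError("zero scored bases: lesion rate undefined")
    if method == "pooled":
        return numerator / denominator
    return sum(rates) / len(rates)


def call_sample_consensus(
    amplicons: Sequence[CloneSet],
    snps: Sequence[SNPObservation] = (),
    ref: ReferenceSegment | None = None,
    require_independent_extractions: bool = True,
    conflict_checker: Callable[[Haplotype, dict[int, tuple[str, bool]]], bool] | None = None,
) -> ConsensusProfile:
    """Call one skeleton's consensus profile from its labelled amplicons.

    A variant enters the consensus only when the per-amplicon consensus
    of at least two amplifications from *independent extractions* carries
    it (falling back to independent PCRs when the sample has a single
    extract and ``require_independent_extractions`` allows it). SNP
    typings are flagged validated when replicated in two extracts.
    """
    if ref is None:
        raise ValueError("a reference segment is required")
    if not amplicons:
        raise ValueError("no amplicons supplied")
    sample_ids = {cs.sample_id for cs in amplicons}
    if len(sample_ids) != 1:
        raise ValueError(f"amplicons mix samples: {sorted(sample_ids)}")
    sample_id = sample_ids.pop()

    notes: list[str] = []
    usable: list[tuple[CloneSet, Haplotype, dict[int, int]]] = []
    for cs in amplicons:
        try:
            consensus, support, ambiguous = per_amplicon_consensus(cs, ref)
        except NoEndogenousSignalError as exc:
            notes.append(str(exc))
            continue
        if ambiguous:
            notes.append(
                f"ambiguous majority at {ambiguous} in "
                f"{cs.extraction_id}/{cs.pcr_id}/f{cs.fragment_id}"
            )
        usable.append((cs, consensus, support))
    if not usable:
        return ConsensusProfile(
            sample_id,
            Haplotype(frozenset(), Window(16126, 16369)),
            status=DISCARDED,
            notes=notes + ["no amplicon retained any non-contaminant clone"],
        )

    n_extracts = len({cs.extraction_id for cs, _, _ in usable})
    independence_key = (
        (lambda cs: cs.extraction_id)
        if require_independent_extractions and n_extracts > 1
        else (lambda cs: (cs.extraction_id, cs.pcr_id))
    )
    if require_independent_extractions and n_extracts == 1:
        notes.append(
            "single extract: accepting independent PCRs as replication units"
        )

    variants: set[Variant] = set()
    support_map: dict[Variant, list[tuple[str, str]]] = {}
    validated_fragments: list[int] = []
    for fragment_id in sorted({cs.fragment_id for cs, _, _ in usable}):
        members = [(cs, h) for cs, h, _ in usable if cs.fragment_id == fragment_id]
        units = {independence_key(cs) for cs, _ in members}
        if len(units) >= 2:
            validated_fragments.append(fragment_id)
        else:
            notes.append(
                f"fragment {fragment_id} amplified in a single replication unit: "
                "excluded from the validated motif"
            )
            continue
        candidates: dict[Variant, set] = defaultdict(set)
        attestations: dict[Variant, list[tuple[str, str]]] = defaultdict(list)
        for cs, h in members:
            for v in h.variants:
                candidates[v].add(independence_key(cs))
                attestations[v].append((cs.extraction_id, cs.pcr_id))
        for v, units_seen in candidates.items():
            if len(units_seen) >= 2:
                variants.add(v)
                support_map[v] = attestations[v]
            else:
                notes.append(
                    f"variant {v.token()} seen in one amplification only: "
                    "non-reproducible, excluded"
                )

    if validated_fragments:
        lo = min(get_amplicon(f).window.lo for f in validated_fragments)
        hi = max(get_amplicon(f).window.hi for f in validated_fragments)
        window = Window(lo, hi)
    else:
        lo = min(cs.amplicon.window.lo for cs, _, _ in usable)
        hi = max(cs.amplicon.window.hi for cs, _, _ in usable)
        window = Window(lo, hi)
        variants = set()

    haplotype = Haplotype(frozenset(variants), window)

    snp_typings: dict[int, tuple[str, bool]] = {}
    by_position: dict[int, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    for obs in snps:
        by_position[obs.position][obs.base].add(obs.extraction_id)
    for position, base_map in by_position.items():
        base = max(base_map, key=lambda b: (len(base_map[b]), b))
        if len(base_map) > 1:
            notes.append(f"discordant SNP typings at {position}: {dict(base_map)}")
        snp_typings[position] = (base, len(base_map[base]) >= 2)

    status = VALIDATED if validated_fragments else PROVISIONAL
    if status == VALIDATED and conflict_checker is not None:
        if conflict_checker(haplotype, snp_typings):
            status = PROVISIONAL
            notes.append("haplogroup-diagnostic SNPs contradict the motif")

    all_records: list[LesionRecord] = []
    for cs, consensus, _ in usable:
        all_records.extend(classify_lesions(cs, consensus, ref))
    rate = lesion_rate([cs for cs, _, _ in usable], all_records, ref)

    return ConsensusProfile(
        sample_id=sample_id,
        haplotype=haplotype,
        support=support_map,
        snp_typings=snp_typings,
        lesion_rate=rate,
        status=status,
        notes=notes,
    )


def screening_decisions(
    amplification_log: dict[str, Sequence[bool]],
) -> dict[str, str]:
    """Apply the screening rule to chronological amplification outcomes.

    A sample is discarded at the first run of two consecutive negative
    amplifications; True = product obtained, False = negative.
    """
    decisions: dict[str, str] = {}
    for sample_id, outcomes in amplification_log.items():
        if not outcomes:
            raise ValueError(f"empty amplification log for {sample_id}")
        discarded = any(
            not outcomes[i] and not outcomes[i + 1] for i in range(len(outcomes) - 1)
        )
        decisions[sample_id] = DISCARDED if discarded else "retained"
    return decisions


def recovery_ratio(n_validated: int, n_skeletons: int) -> float:
    """Endogenous-DNA recovery ratio in percent, to one decimal.

    The denominator is skeletons sampled, not extracts performed.
    """
    if n_skeletons <= 0:
        raise ValueError("skeleton roster is empty")
    if not 0 <= n_validated <= n_skeletons:
        raise ValueError("validated count outside [0, roster size]")
    return round(100.0 * n_validated / n_skeletons, 1)


def screening_and_recovery(
    amplification_log: dict[str, Sequence[bool]],
    skeleton_roster: Sequence[str],
    validated_samples: Iterable[str],
) -> tuple[dict[str, str], float]:
    """Screening decisions plus the overall recovery ratio."""
    decisions = screening_decisions(amplification_log)
    ratio = recovery_ratio(len(set(validated_samples)), len(skeleton_roster))
    return decisions, ratio
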