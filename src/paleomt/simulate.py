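"""Synthetic-data generator with known ground truth.

Emulates every input the pipeline consumes: multi-population HVS1
haplotype databases, staff contamination panels, and clone experiments
with planted miscoding lesions, staff contaminants and carry-over
clones.

The population model is deliberately simple: each haplogroup category
has a founder motif, and individual haplotypes are the founder plus a
Poisson number of private, transition-biased substitutions (a star
phylogeny).  That is enough to produce the haplotype-sharing and FST
structure the comparative analyses consume; it makes no claim to
realistic coalescent genealogies.  Damage is independent per clone and
scored site, with the type-2 (C->T / G->A deamination) fraction
configurable; there is no fragment-end enrichment, since the lesion
counting downstream has no positional model either.

Every emission is a pure function of (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (
    COMPLETE_WINDOW,
    Haplotype,
    ReferenceSegment,
    Variant,
    parse_motif,
    transition_partner,
    trim_to_window,
)
from .consensus import CloneRead, CloneSet, StaffPanel
from .popgen import DBRecord, HaplotypeDatabase, PopulationMeta
from .reference import AMPLICONS, synthetic_reference

#: Default founder motifs per haplogroup category (within the HVS1 window).
DEFAULT_FOUNDERS: dict[str, str] = {
    "H": "CRS",
    "K": "16224C 16311C",
    "U5": "16270T",
    "J": "16126C",
    "T": "16126C 16294T",
    "R0": "16293C",
    "N*": "16356C",
    "L3": "16223T",
    "AS": "16223T 16319A",
    "AF": "16187T 16223T 16278T",
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions.

    ``clones_range`` (10-15 clones per amplicon), two extracts per
    skeleton and two PCRs per extract mirror the laboratory design the
    pipeline was built to validate; ``mu`` is the mean number of private
    mutations per lineage; ``transition_fraction`` biases them toward
    transitions as observed in the control region.
    """

    seed: int
    n_populations: int = 5
    sample_size: int = 100
    founders: tuple[tuple[str, str], ...] = tuple(DEFAULT_FOUNDERS.items())
    dirichlet_concentration: float = 1.0
    mu: float = 0.4
    transition_fraction: float = 0.9
    damage_rate: float = 0.005
    type2_fraction: float = 0.85
    staff_contaminant_fraction: float = 0.10
    carry_over_fraction: float = 0.0
    clones_range: tuple[int, int] = (10, 15)
    n_extracts: int = 2
    pcrs_per_extract: int = 2

    def __post_init__(self) -> None:
        for name in (
            "mu", "transition_fraction", "damage_rate", "type2_fraction",
            "staff_contaminant_fraction", "carry_over_fraction",
        ):
            value = getattr(self, name)
            if name == "mu":
                if value < 0:
                    raise ValueError("mu must be non-negative")
            elif not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        lo, hi = self.clones_range
        if not (1 <= lo <= hi <= 50):
            raise ValueError("clones_range must lie within [1, 50]")
        if self.sample_size < 1:
            raise ValueError("sample size must be positive")
        if self.staff_contaminant_fraction + self.carry_over_fraction > 1.0:
            raise ValueError("contaminant fractions sum above 1")


@dataclass
class SimulatedTruth:
    """Ground truth for every emitted record."""

    individuals: dict[str, tuple[Haplotype, str]] = field(default_factory=dict)
    clone_origins: dict[str, str] = field(default_factory=dict)
    clone_lesions: dict[str, list[tuple[int, str, str]]] = field(default_factory=dict)
    staff_collisions: list[str] = field(default_factory=list)


def _mutable_positions(ref: ReferenceSegment, forbidden: set[int]) -> list[int]:
    return [
        p
        for p in COMPLETE_WINDOW.positions()
        if not ref.is_excluded(p) and p not in forbidden
    ]


def _mutate(
    h: Haplotype,
    n_mutations: int,
    ref: ReferenceSegment,
    rng: np.random.Generator,
    transition_fraction: float,
) -> Haplotype:
    """Add private substitutions at positions the haplotype does not use."""
    variants = dict((v.position, v) for v in h.variants)
    candidates = _mutable_positions(ref, set(variants))
    if n_mutations <= 0 or not candidates:
        return h
    n_mutations = min(n_mutations, len(candidates))
    chosen = rng.choice(candidates, size=n_mutations, replace=False)
    for position in map(int, chosen):
        base = ref.base(position)
        if rng.random() < transition_fraction:
            derived = transition_partner(base)
        else:
            derived = str(rng.choice([b for b in "ACGT" if b not in (base, transition_partner(base))]))
        variants[position] = Variant(position, derived)
    return Haplotype(frozenset(variants.values()), h.window)


def simulate_database(
    cfg: SimulationConfig,
    ref: ReferenceSegment | None = None,
) -> tuple[HaplotypeDatabase, SimulatedTruth]:
    """Simulate a multi-population haplotype database.

    Per population, haplogroup counts are multinomial over a Dirichlet
    draw of category frequencies; each individual carries its category's
    founder motif plus Poisson(mu) private transition-biased variants.
    """
    if ref is None:
        ref = synthetic_reference()
    rng = np.random.default_rng(cfg.seed)
    founders = [(label, parse_motif(motif)) for label, motif in cfg.founders]
    truth = SimulatedTruth()
    records: list[DBRecord] = []
    metadata: dict[str, PopulationMeta] = {}
    concentration = np.full(len(founders), cfg.dirichlet_concentration, dtype=float)
    for p in range(cfg.n_populations):
        population_id = f"pop-{p + 1}"
        freqs = rng.dirichlet(concentration)
        counts = rng.multinomial(cfg.sample_size, freqs)
        metadata[population_id] = PopulationMeta(
            region="simulated",
            latitude=float(rng.uniform(30.0, 50.0)),
            longitude=float(rng.uniform(20.0, 50.0)),
            geographic_ok=True,
        )
        i = 0
        for (label, founder), count in zip(founders, counts):
            for _ in range(count):
                i += 1
                individual_id = f"{population_id}-ind-{i}"
                n_private = int(rng.poisson(cfg.mu))
                h = _mutate(founder, n_private, ref, rng, cfg.transition_fraction)
                truth.individuals[individual_id] = (h, label)
                records.append(DBRecord(individual_id, population_id, h, label))
    return HaplotypeDatabase(records, metadata), truth


def simulate_staff_panel(
    n_people: int,
    cfg: SimulationConfig,
    ref: ReferenceSegment | None = None,
    avoid: Sequence[Haplotype] = (),
    force_collision_with: Haplotype | None = None,
) -> tuple[StaffPanel, SimulatedTruth]:
    """Random staff HVS1 motifs, distinct and disjoint from ``avoid``.

    With ``force_collision_with`` the first panel member deliberately
    shares that motif (flagged in the returned truth), to exercise the
    awkward real-world case of a handler matching an ancient type.
    """
    if n_people < 1:
        raise ValueError("need at least one staff member")
    if ref is None:
        ref = synthetic_reference()
    rng = np.random.default_rng(cfg.seed + 104729)
    truth = SimulatedTruth()
    avoid_keys = {h.variants for h in avoid}
    members: list[tuple[str, Haplotype]] = []
    seen: set[frozenset] = set()
    start = 0
    if force_collision_with is not None:
        members.append(("staff-1", force_collision_with))
        seen.add(force_collision_with.variants)
        truth.staff_collisions.append("staff-1")
        start = 1
    crs = Haplotype(frozenset(), COMPLETE_WINDOW)
    for i in range(start, n_people):
        while True:
            n_variants = 2 + int(rng.integers(0, 3))
            h = _mutate(crs, n_variants, ref, rng, cfg.transition_fraction)
            if h.variants not in seen and h.variants not in avoid_keys:
                break
        seen.add(h.variants)
        members.append((f"staff-{i + 1}", h))
    return StaffPanel(members), truth


def _plant_lesions(
    h: Haplotype,
    cfg: SimulationConfig,
    scored_positions: Sequence[int],
    ref: ReferenceSegment,
    rng: np.random.Generator,
) -> tuple[Haplotype, list[tuple[int, str, str]]]:
    """Bernoulli(damage_rate) lesions per scored site, type-2 biased.

    Each lesion targets, with probability ``type2_fraction``, a site
    whose template base is C or G (becoming T or A); otherwise an A/T
    site (becoming G or C).  The template base is the clone's own base,
    so lesions can also revert a true variant toward the reference.
    """
    n_lesions = int(rng.binomial(len(scored_positions), cfg.damage_rate))
    if n_lesions == 0:
        return h, []
    variants = {v.position: v for v in h.variants}

    def template_base(position: int) -> str:
        v = variants.get(position)
        return v.derived if v is not None else ref.base(position)

    cg_sites = [p for p in scored_positions if template_base(p) in "CG"]
    at_sites = [p for p in scored_positions if template_base(p) in "AT"]
    lesions: list[tuple[int, str, str]] = []
    hit: set[int] = set()
    for _ in range(n_lesions):
        pool = cg_sites if rng.random() < cfg.type2_fraction else at_sites
        pool = [p for p in pool if p not in hit]
        if not pool:
            continue
        position = int(pool[rng.integers(0, len(pool))])
        hit.add(position)
        before = template_base(position)
        after = transition_partner(before)
        lesions.append((position, before, after))
        if after == ref.base(position):
            variants.pop(position, None)
        else:
            variants[position] = Variant(position, after)
    return Haplotype(frozenset(variants.values()), h.window), lesions


def simulate_clone_experiment(
    sample_id: str,
    truth_haplotype: Haplotype,
    cfg: SimulationConfig,
    staff: StaffPanel | None = None,
    neighbors: Sequence[tuple[str, Haplotype]] = (),
    ref: ReferenceSegment | None = None,
    batch_id: str = "batch-1",
    seed: int | None = None,
) -> tuple[list[CloneSet], SimulatedTruth]:
    """Simulate all cloned amplifications for one skeleton.

    Produces n_extracts x pcrs_per_extract x 2 fragments clone sets.
    Per clone: with the configured probabilities it is replaced by a
    staff motif or a batch neighbour's motif; otherwise it is the true
    haplotype carrying planted lesions.  Truth labels and lesion
    positions are recorded for every clone.
    """
    if ref is None:
        ref = synthetic_reference()
    if not AMPLICONS:
        raise ValueError("no amplicon definitions registered")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    truth = SimulatedTruth()
    truth.individuals[sample_id] = (truth_haplotype, "")
    staff_motifs = [h for _, h in (staff.members if staff else [])]
    neighbor_motifs = [(sid, h) for sid, h in neighbors if sid != sample_id]

    clone_sets: list[CloneSet] = []
    lo, hi = cfg.clones_range
    for e in range(1, cfg.n_extracts + 1):
        for p in range(1, cfg.pcrs_per_extract + 1):
            for fragment_id, amplicon in sorted(AMPLICONS.items()):
                scored = amplicon.scored_positions(ref)
                # the PCR amplifies the whole fragment, so clones cover the
                # amplicon window even when the truth motif is partial
                local_truth = Haplotype(
                    frozenset(
                        v for v in truth_haplotype.variants
                        if v.position in amplicon.window
                    ),
                    amplicon.window,
                )
                n_clones = int(rng.integers(lo, hi + 1))
                clones = []
                for c in range(1, n_clones + 1):
                    clone_id = f"{sample_id}-E{e}-P{p}-F{fragment_id}-C{c}"
                    u = rng.random()
                    if staff_motifs and u < cfg.staff_contaminant_fraction:
                        donor = staff_motifs[int(rng.integers(0, len(staff_motifs)))]
                        h = trim_to_window(donor, amplicon.window)
                        truth.clone_origins[clone_id] = "staff_contaminant"
                        lesions: list[tuple[int, str, str]] = []
                    elif (
                        neighbor_motifs
                        and u < cfg.staff_contaminant_fraction + cfg.carry_over_fraction
                    ):
                        _, donor = neighbor_motifs[int(rng.integers(0, len(neighbor_motifs)))]
                        h = trim_to_window(donor, amplicon.window)
                        truth.clone_origins[clone_id] = "carry_over"
                        lesions = []
                    else:
                        h, lesions = _plant_lesions(local_truth, cfg, scored, ref, rng)
                        truth.clone_origins[clone_id] = "endogenous"
                    truth.clone_lesions[clone_id] = lesions
                    clones.append(
                        CloneRead(
                            clone_id=clone_id,
                            sample_id=sample_id,
                            extraction_id=f"E{e}",
                            pcr_id=f"E{e}-P{p}",
                            fragment_id=fragment_id,
                            haplotype=h,
                        )
                    )
                clone_sets.append(CloneSet(clones, batch_id=batch_id))
    return clone_sets, truth


def build_fixture_suite(out_dir, seed: int = 20140605) -> dict[str, str]:
    """Write the packaged fixtures to ``out_dir`` and return checksums.

    Emits (1) the 15-profile study fixture, (2) a small synthetic
    multi-population database with its ground truth, and (3) one
    synthetic clone experiment, all as plain text with a manifest of
    SHA-256 checksums.  Regeneration with the same seed is byte-identical.
    """
    from . import io as pio
    from .fixtures import load_ppnb_profiles, profiles_path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    files: dict[str, Path] = {}
    fixture = out / "ppnb_profiles.tsv"
    fixture.write_text(Path(profiles_path()).read_text())
    files["ppnb_profiles.tsv"] = fixture

    cfg = replace(_small_config(seed))
    db, truth = simulate_database(cfg)
    files["synthetic_database.csv"] = out / "synthetic_database.csv"
    pio.write_database_csv(files["synthetic_database.csv"], db)
    files["synthetic_populations.csv"] = out / "synthetic_populations.csv"
    pio.write_population_metadata_csv(files["synthetic_populations.csv"], db)
    files["synthetic_truth.json"] = out / "synthetic_truth.json"
    files["synthetic_truth.json"].write_text(
        json.dumps(
            {
                ind: {"motif": h.motif(), "haplogroup": label}
                for ind, (h, label) in sorted(truth.individuals.items())
            },
            indent=1,
        )
    )

    profiles = load_ppnb_profiles()
    staff, _ = simulate_staff_panel(7, cfg)
    clone_sets, clone_truth = simulate_clone_experiment(
        "synthetic-skeleton-1",
        profiles[0].haplotype,
        cfg,
        staff=staff,
        seed=seed + 1,
    )
    files["synthetic_clones.tsv"] = out / "synthetic_clones.tsv"
    pio.write_clones_tsv(files["synthetic_clones.tsv"], clone_sets)
    files["synthetic_clone_truth.json"] = out / "synthetic_clone_truth.json"
    files["synthetic_clone_truth.json"].write_text(
        json.dumps(dict(sorted(clone_truth.clone_origins.items())), indent=1)
    )
    files["staff_panel.tsv"] = out / "staff_panel.tsv"
    pio.write_motif_tsv(
        files["staff_panel.tsv"],
        [(pid, h, "") for pid, h in staff.members],
    )

    checksums = {
        name: hashlib.sha256(path.read_bytes()).hexdigest()
        for name, path in sorted(files.items())
    }
    (out / "MANIFEST.json").write_text(json.dumps(checksums, indent=1))
    return checksums


def _small_config(seed: int) -> SimulationConfig:
    return SimulationConfig(seed=seed, n_populations=4, sample_size=40)
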