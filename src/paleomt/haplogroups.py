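"""Decision-table mtDNA haplogroup assignment and frequency tabulation.

Haplogroups are assigned from two evidence streams: the HVS1 motif and a
small panel of diagnostic coding-region SNPs (7028, 12308, 14766, 10873,
10550, 12705, 10398, 10400, 4646).  Instead of embedding a full mtDNA
phylogeny, the classifier walks a small, user-editable decision table
whose rules encode exactly the clade-defining states this panel can
resolve (L3, N*, K, U*, H, HV, R0).  SNP evidence outranks motif
evidence; a call that rests solely on unreplicated SNP typings is
assigned but not *firm*.

Rule semantics
--------------
A rule lists required SNP alleles and (optionally) required motif
variants.  A profile is a *candidate* for a rule when no typed SNP
contradicts the rule and at least one required SNP is positively typed
(for rules without SNP conditions, the motif requirement must be fully
observed instead).  Untyped SNPs and motif positions outside the covered
window are wildcards.  Among candidate rules, those whose motif
conditions are fully observed rank first, then rules whose motif is
merely untested, then rules whose motif is contradicted; ties break by
priority.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import Haplotype, Variant

#: The registered coding-region SNP panel.
SNP_PANEL = frozenset({7028, 12308, 14766, 10873, 10550, 12705, 10398, 10400, 4646})

UNASSIGNED = "unassigned"

CONSISTENT = "consistent"
CONFLICT = "conflict"
UNTESTABLE = "untestable"


class DecisionTableError(ValueError):
    """Malformed decision table."""


class UnmappedLabelError(KeyError):
    """A haplogroup label has no entry in the grouping scheme."""


@dataclass(frozen=True)
class SNPTyping:
    """Typed coding-region SNPs: position -> (base, validated flag)."""

    calls: Mapping[int, tuple[str, bool]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for position, (base, _) in self.calls.items():
            if position not in SNP_PANEL:
                raise ValueError(f"position {position} not in the registered SNP panel")
            if base not in "ACGT":
                raise ValueError(f"SNP base {base!r} at {position} not in A,C,G,T")

    def base(self, position: int) -> str | None:
        entry = self.calls.get(position)
        return entry[0] if entry else None

    def validated(self, position: int) -> bool:
        entry = self.calls.get(position)
        return bool(entry and entry[1])

    def __bool__(self) -> bool:
        return bool(self.calls)


@dataclass(frozen=True)
class Rule:
    label: str
    priority: int
    snp_conditions: tuple[tuple[int, str], ...]
    motif_conditions: frozenset[Variant]

    def __post_init__(self) -> None:
        if not self.snp_conditions and not self.motif_conditions:
            raise DecisionTableError(f"rule {self.label!r} has no conditions")


@dataclass(frozen=True)
class DecisionTable:
    rules: tuple[Rule, ...]

    def __post_init__(self) -> None:
        labels = [r.label for r in self.rules]
        if len(set(labels)) != len(labels):
            raise DecisionTableError("duplicate rule labels in decision table")

    def sorted_rules(self) -> list[Rule]:
        return sorted(self.rules, key=lambda r: r.priority)


@dataclass
class HaplogroupCall:
    label: str = UNASSIGNED
    basis: str = "none"  # snp | motif | both | none
    firm: bool = False
    consistency: str = UNTESTABLE
    reasons: list[str] = field(default_factory=list)

    @property
    def assigned(self) -> bool:
        return self.label != UNASSIGNED


def _parse_snp_conditions(text: str | None, line: int) -> tuple[tuple[int, str], ...]:
    text = (text or "").strip()
    if not text:
        return ()
    out = []
    for item in text.split(";"):
        item = item.strip()
        if "=" not in item:
            raise DecisionTableError(f"line {line}: bad SNP condition {item!r}")
        pos_s, base = item.split("=", 1)
        try:
            position = int(pos_s)
        except ValueError:
            raise DecisionTableError(f"line {line}: bad SNP position {pos_s!r}") from None
        base = base.strip().upper()
        if base not in "ACGT":
            raise DecisionTableError(f"line {line}: bad SNP allele {base!r}")
        out.append((position, base))
    return tuple(out)


def _parse_motif_conditions(text: str | None, line: int) -> frozenset[Variant]:
    text = (text or "").strip()
    if not text:
        return frozenset()
    variants = []
    for token in text.replace(";", " ").split():
        try:
            variants.append(Variant(int(token[:-1]), token[-1]))
        except (ValueError, IndexError):
            raise DecisionTableError(
                f"line {line}: bad motif condition token {token!r}"
            ) from None
    return frozenset(variants)


def load_decision_table(path) -> DecisionTable:
    """Load a decision table from TSV.

    Columns: ``label``, ``priority``, ``snp_conditions``
    (``pos=BASE;pos=BASE``), ``motif_conditions`` (space- or
    ``;``-separated motif tokens).
    """
    rules = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"label", "priority", "snp_conditions", "motif_conditions"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise DecisionTableError(
                f"decision table must have columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            rules.append(
                Rule(
                    label=row["label"].strip(),
                    priority=int(row["priority"]),
                    snp_conditions=_parse_snp_conditions(row["snp_conditions"], i),
                    motif_conditions=_parse_motif_conditions(row["motif_conditions"], i),
                )
            )
    if not rules:
        raise DecisionTableError("decision table contains no rules")
    return DecisionTable(tuple(rules))


def _data_path(name: str) -> Path:
    return Path(str(resources.files("paleomt").joinpath("data", name)))


def default_decision_table() -> DecisionTable:
    """The packaged decision table covering the PPNB-relevant clades."""
    return load_decision_table(_data_path("decision_table.tsv"))


# --- rule matching ---------------------------------------------------------

_MOTIF_ATTESTED = 0
_MOTIF_UNTESTED = 1
_MOTIF_CONTRADICTED = 2


def _snp_status(rule: Rule, s: SNPTyping) -> tuple[bool, list[tuple[int, str]]]:
    """(compatible, positively matched conditions)."""
    positives = []
    for position, allele in rule.snp_conditions:
        typed = s.base(position)
        if typed is None:
            continue
        if typed != allele:
            return False, []
        positives.append((position, allele))
    return True, positives


def _motif_status(rule: Rule, h: Haplotype) -> tuple[int, list[Variant]]:
    """Motif tier (attested/untested/contradicted) and observed conditions."""
    if not rule.motif_conditions:
        return _MOTIF_UNTESTED, []
    observed = []
    contradicted = False
    for v in rule.motif_conditions:
        if v.position not in h.window:
            continue  # outside coverage: wildcard
        if v in h.variants:
            observed.append(v)
        else:
            contradicted = True
    if contradicted:
        return _MOTIF_CONTRADICTED, observed
    if len(observed) == len(rule.motif_conditions):
        return _MOTIF_ATTESTED, observed
    return _MOTIF_UNTESTED, observed


def classify_profile(
    h: Haplotype,
    s: SNPTyping | Mapping[int, tuple[str, bool]] | None,
    table: DecisionTable | None = None,
) -> HaplogroupCall:
    """Assign a haplogroup from an HVS1 motif plus coding-region SNPs.

    Returns an unassigned call (not an error) when no rule is positively
    supported.  The call is *firm* when at least one deciding SNP is
    validated, or when the decision does not rest on SNP evidence at all.
    """
    if table is None:
        table = default_decision_table()
    if s is None:
        s = SNPTyping({})
    elif not isinstance(s, SNPTyping):
        s = SNPTyping(dict(s))

    candidates = []
    for rule in table.sorted_rules():
        compatible, snp_positives = _snp_status(rule, s)
        if not compatible:
            continue
        motif_tier, motif_positives = _motif_status(rule, h)
        if rule.snp_conditions:
            if not snp_positives:
                continue
        elif motif_tier != _MOTIF_ATTESTED:
            continue
        candidates.append((motif_tier, rule.priority, rule, snp_positives, motif_positives))

    if not candidates:
        return HaplogroupCall(reasons=["no rule positively supported"])

    candidates.sort(key=lambda item: (item[0], item[1]))
    motif_tier, _, rule, snp_positives, motif_positives = candidates[0]

    if snp_positives and motif_positives:
        basis = "both"
    elif snp_positives:
        basis = "snp"
    else:
        basis = "motif"

    if not snp_positives:
        firm = True  # decision independent of SNP evidence
    else:
        firm = any(s.validated(position) for position, _ in snp_positives)

    call = HaplogroupCall(label=rule.label, basis=basis, firm=firm)
    call.reasons = [
        f"rule {rule.label}: SNP support {['%d%s' % p for p in snp_positives]}, "
        f"motif support {[v.token() for v in motif_positives]}"
    ]
    return call


def consistency_check(
    h: Haplotype,
    s: SNPTyping | Mapping[int, tuple[str, bool]] | None,
    call: HaplogroupCall,
    table: DecisionTable | None = None,
) -> HaplogroupCall:
    """Check phylogenetic agreement between motif- and SNP-implied clades.

    Motif-implied candidates are rules whose motif conditions are fully
    observed in the covered window; SNP-implied candidates are rules
    positively supported and uncontradicted by typed SNPs.  Disjoint sets
    flag a conflict; an empty side makes the check untestable.
    """
    if table is None:
        table = default_decision_table()
    if s is None:
        s = SNPTyping({})
    elif not isinstance(s, SNPTyping):
        s = SNPTyping(dict(s))

    motif_implied = {
        rule.label
        for rule in table.rules
        if _motif_status(rule, h)[0] == _MOTIF_ATTESTED
    }
    snp_implied = set()
    for rule in table.rules:
        compatible, positives = _snp_status(rule, s)
        if compatible and positives:
            snp_implied.add(rule.label)

    if not motif_implied or not snp_implied:
        call.consistency = UNTESTABLE
    elif motif_implied & snp_implied:
        call.consistency = CONSISTENT
    else:
        call.consistency = CONFLICT
        call.reasons.append(
            f"motif-implied {sorted(motif_implied)} disjoint from "
            f"SNP-implied {sorted(snp_implied)}"
        )
    return call


# --- grouping and frequencies ---------------------------------------------

#: The 25 pooled haplogroup categories used for frequency comparison.
CATEGORIES = (
    "AS", "H", "AF", "K", "U5", "HV0", "HV", "J", "T", "N*", "N1", "U7",
    "U3", "U1", "U6", "R0", "U4", "U2", "R+", "X", "U+", "W", "U*", "I", "N2",
)


def load_grouping(path) -> dict[str, str]:
    """Load a raw-label -> pooled-category map from two-column TSV."""
    grouping: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or {"raw_label", "category"} - set(reader.fieldnames):
            raise DecisionTableError(
                "grouping scheme needs columns raw_label, category"
            )
        for row in reader:
            grouping[row["raw_label"].strip()] = row["category"].strip()
    return grouping


def default_grouping() -> dict[str, str]:
    return load_grouping(_data_path("haplogroup_grouping.tsv"))


def group_label(label: str, grouping: Mapping[str, str]) -> str:
    """Map a raw haplogroup label to its pooled category."""
    if label in grouping:
        return grouping[label]
    # sub-clades fall back to their longest mapped prefix (K1a -> K).
    for cut in range(len(label) - 1, 0, -1):
        if label[:cut] in grouping:
            return grouping[label[:cut]]
    raise UnmappedLabelError(f"haplogroup label {label!r} has no grouping entry")


def haplogroup_frequencies(
    records: Iterable[tuple[str, str]],
    grouping: Mapping[str, str] | None = None,
    categories: Sequence[str] = CATEGORIES,
) -> "pd.DataFrame":
    """Absolute and relative pooled-category frequencies per population.

    ``records`` are (population, haplogroup label) pairs — for the
    ancient sample, firm calls only.  Returns a DataFrame indexed by
    population with one column per category plus ``n``; relative
    frequencies are in percent and sum to 100 per population.
    """
    import pandas as pd

    if grouping is None:
        grouping = default_grouping()
    counts: dict[str, dict[str, int]] = {}
    for population, label in records:
        category = group_label(label, grouping)
        if category not in categories:
            raise UnmappedLabelError(
                f"category {category!r} not among the configured categories"
            )
        counts.setdefault(population, {c: 0 for c in categories})
        counts[population][category] += 1
    if not counts:
        raise ValueError("no records to tabulate")
    absolute = pd.DataFrame.from_dict(counts, orient="index")[list(categories)]
    absolute["n"] = absolute.sum(axis=1)
    relative = absolute[list(categories)].div(absolute["n"], axis=0) * 100.0
    relative["n"] = absolute["n"]
    return pd.concat({"absolute": absolute, "relative": relative}, axis=1)


def relative_frequencies(table) -> "pd.DataFrame":
    """The percent block of a :func:`haplogroup_frequencies` table."""
    return table["relative"].drop(columns="n")


def bootstrap_ci(
    labels: Sequence[str],
    categories: Sequence[str] = CATEGORIES,
    grouping: Mapping[str, str] | None = None,
    B: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
) -> dict[str, tuple[float, float]]:
    """Non-parametric bootstrap percentile CI of category frequencies.

    Individuals are resampled with replacement ``B`` times; the interval
    is the percentile interval of the relative frequency (percent).
    """
    if not labels:
        raise ValueError("empty population")
    if B < 100:
        raise ValueError("B must be at least 100")
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    if grouping is None:
        grouping = default_grouping()
    pooled = [group_label(l, grouping) for l in labels]
    index = {c: i for i, c in enumerate(categories)}
    codes = np.array([index[c] for c in pooled])
    n = len(codes)
    rng = np.random.default_rng(seed)
    resamples = rng.integers(0, n, size=(B, n))
    freqs = np.zeros((B, len(categories)))
    for b in range(B):
        counts = np.bincount(codes[resamples[b]], minlength=len(categories))
        freqs[b] = 100.0 * counts / n
    alpha = (1.0 - level) / 2.0
    lo = np.percentile(freqs, 100 * alpha, axis=0)
    hi = np.percentile(freqs, 100 * (1 - alpha), axis=0)
    return {c: (float(lo[i]), float(hi[i])) for c, i in index.items()}
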