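"""Reference segment and amplicon registry for the HVS1 pipeline.

The package ships no copy of the genuine rCRS. Sequence-level operations
in the test-bed run against a *synthetic* HVS1-like reference segment:
a deterministic random sequence in which every position that any packaged
motif, decision rule or simulator founder touches is pinned to the true
rCRS base, so motif arithmetic on packaged data is exact. For analyses of
real sequence data, load the genuine rCRS segment from FASTA with
:func:`reference_from_fasta`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import POLYC_EXCLUSION, ReferenceSegment, Window

#: True rCRS bases at the positions used by packaged motifs, decision
#: rules and simulator founder haplotypes (1-based rCRS coordinates).
RCRS_PINNED_BASES: dict[int, str] = {
    16126: "T",
    16129: "G",
    16187: "C",
    16189: "T",
    16192: "C",
    16209: "T",
    16223: "C",
    16224: "T",
    16230: "A",
    16249: "T",
    16256: "C",
    16270: "C",
    16278: "C",
    16290: "C",
    16293: "A",
    16294: "C",
    16298: "T",
    16304: "T",
    16311: "T",
    16319: "G",
    16327: "C",
    16356: "T",
    16362: "T",
    16366: "C",
}

#: Span of the amplified HVS1 region (outer primers sit outside it).
AMPLIFIED_REGION = (16095, 16399)


@dataclass(frozen=True)
class Amplicon:
    """One registered PCR fragment.

    ``window`` is the informative span used for haplotype calling;
    ``primer_sites`` are the annealing stretches flanking it, excluded
    from lesion scoring because primer-templated bases do not report on
    the endogenous molecule.
    """

    fragment_id: int
    window: Window
    primer_sites: tuple[Window, ...]

    def scored_positions(self, ref: ReferenceSegment) -> list[int]:
        """Positions contributing to lesion denominators."""
        out = []
        for position in self.window.positions():
            if any(position in w for w in self.primer_sites):
                continue
            if ref.is_excluded(position):
                continue
            out.append(position)
        return out


#: The two overlapping HVS1 fragments used for all cloned amplifications.
FRAGMENT_1 = Amplicon(1, Window(16126, 16258), (Window(16095, 16125),))
FRAGMENT_2 = Amplicon(2, Window(16258, 16369), (Window(16370, 16399),))

AMPLICONS: dict[int, Amplicon] = {1: FRAGMENT_1, 2: FRAGMENT_2}


def get_amplicon(fragment_id: int) -> Amplicon:
    try:
        return AMPLICONS[fragment_id]
    except KeyError:
        raise KeyError(
            f"fragment {fragment_id!r} is not a registered amplicon (known: 1, 2)"
        ) from None


def synthetic_reference(
    start: int = AMPLIFIED_REGION[0],
    end: int = AMPLIFIED_REGION[1],
    seed: int = 20140605,
) -> ReferenceSegment:
    """Deterministic HVS1-like reference segment (synthetic filler).

    Positions listed in :data:`RCRS_PINNED_BASES` carry the genuine rCRS
    base; all other positions are arbitrary (seeded) filler. Suitable for
    simulation and for round-trip sequence<->motif arithmetic on the
    packaged data; not a substitute for the genuine rCRS when analysing
    real reads.
    """
    rng = np.random.default_rng(seed)
    bases = rng.choice(list("ACGT"), size=end - start + 1)
    seq = list(map(str, bases))
    for position, base in RCRS_PINNED_BASES.items():
        if start <= position <= end:
            seq[position - start] = base
    return ReferenceSegment(
        name="synthetic-rCRS-HVS1",
        start=start,
        sequence="".join(seq),
        polyc_exclusion=Window(*POLYC_EXCLUSION),
    )


def reference_from_fasta(path, name: str | None = None, start: int = 16024) -> ReferenceSegment:
    """Load a reference segment from a single-record FASTA.

    ``start`` is the rCRS coordinate of the first base of the record.
    A header of the form ``>name start=16024`` overrides it.
    """
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    header_fields = dict(
        part.split("=", 1) for part in record.description.split() if "=" in part
    )
    if "start" in header_fields:
        start = int(header_fields["start"])
    return ReferenceSegment(
        name=name or record.id,
        start=start,
        sequence=str(record.seq).upper(),
        polyc_exclusion=Window(*POLYC_EXCLUSION),
    )
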