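"""The packaged study fixture: 15 PPNB consensus profiles.

Fifteen validated mtDNA profiles from the Pre-Pottery Neolithic B sites
of Tell Halula and Tell Ramad (Syria): HVS1 motifs with their covered
windows, nine-position coding-region SNP typings with replication
flags, and the published haplogroup labels.  H53's haplogroup rests
solely on SNP typings that were not replicated across extracts, so its
call is expected to be assigned but not firm.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .core import Haplotype, Window, parse_motif
from .haplogroups import SNPTyping


@dataclass(frozen=True)
class StudyProfile:
    site: str
    sample_id: str
    haplotype: Haplotype
    snp_typing: SNPTyping
    expected_haplogroup: str


def profiles_path() -> Path:
    return Path(str(resources.files("paleomt").joinpath("data", "ppnb_profiles.tsv")))


def _parse_snp_field(text: str) -> SNPTyping:
    calls = {}
    text = text.strip()
    if text:
        for item in text.split(","):
            pos_s, base, flag = item.split(":")
            calls[int(pos_s)] = (base, flag == "1")
    return SNPTyping(calls)


def load_ppnb_profiles(path=None) -> list[StudyProfile]:
    """Load the 15-profile study fixture."""
    import csv

    if path is None:
        path = profiles_path()
    profiles = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            window = Window(int(row["window_lo"]), int(row["window_hi"]))
            profiles.append(
                StudyProfile(
                    site=row["site"],
                    sample_id=row["sample_id"],
                    haplotype=parse_motif(row["motif"], window),
                    snp_typing=_parse_snp_field(row["snp_typings"]),
                    expected_haplogroup=row["expected_haplogroup"],
                )
            )
    if len(profiles) != 15:
        raise ValueError(f"study fixture should contain 15 profiles, found {len(profiles)}")
    return profiles


#: Number of skeletons sampled across the three excavated sites.
SKELETONS_SAMPLED = 63
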