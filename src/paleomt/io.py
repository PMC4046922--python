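"""Plain-text interchange formats used between pipeline stages.

Motifs travel as TSV (sample_id, motif, window_lo, window_hi,
haplogroup); clone sequences as FASTA with structured headers
``sample|extraction|pcr|fragment|clone`` or as long-format TSV; the
haplotype database and population metadata as CSV.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

from .consensus import CloneRead, CloneSet, StaffPanel
from .core import (
    COMPLETE_WINDOW,
    Haplotype,
    ReferenceSegment,
    Window,
    format_motif,
    parse_motif,
    sequence_from_variants,
    variants_from_sequence,
)
from .popgen import DBRecord, HaplotypeDatabase, PopulationMeta
from .reference import get_amplicon


# --- motif TSV ---------------------------------------------------------------


def write_motif_tsv(path, rows: Iterable[tuple[str, Haplotype, str]]) -> None:
    """Rows are (sample_id, haplotype, haplogroup label or '')."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "motif", "window_lo", "window_hi", "haplogroup"])
        for sample_id, h, haplogroup in rows:
            writer.writerow(
                [sample_id, format_motif(h), h.window.lo, h.window.hi, haplogroup]
            )


def read_motif_tsv(path) -> list[tuple[str, Haplotype, str]]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            window = Window(int(row["window_lo"]), int(row["window_hi"]))
            out.append(
                (
                    row["sample_id"],
                    parse_motif(row["motif"], window),
                    row.get("haplogroup", "") or "",
                )
            )
    return out


def read_staff_panel(path) -> StaffPanel:
    return StaffPanel([(sid, h) for sid, h, _ in read_motif_tsv(path)])


# --- clones ------------------------------------------------------------------

CLONE_COLUMNS = [
    "sample_id", "extraction_id", "pcr_id", "fragment_id",
    "clone_id", "motif", "batch_id",
]


def write_clones_tsv(path, clone_sets: Sequence[CloneSet]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CLONE_COLUMNS)
        for cs in clone_sets:
            for c in cs.clones:
                writer.writerow(
                    [
                        c.sample_id, c.extraction_id, c.pcr_id, c.fragment_id,
                        c.clone_id, format_motif(c.haplotype), cs.batch_id,
                    ]
                )


def read_clones_tsv(path) -> list[CloneSet]:
    groups: dict[tuple, list[CloneRead]] = defaultdict(list)
    batches: dict[tuple, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(CLONE_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"clone TSV missing columns: {sorted(missing)}")
        for row in reader:
            fragment_id = int(row["fragment_id"])
            window = get_amplicon(fragment_id).window
            key = (
                row["sample_id"], row["extraction_id"], row["pcr_id"], fragment_id,
            )
            groups[key].append(
                CloneRead(
                    clone_id=row["clone_id"],
                    sample_id=row["sample_id"],
                    extraction_id=row["extraction_id"],
                    pcr_id=row["pcr_id"],
                    fragment_id=fragment_id,
                    haplotype=parse_motif(row["motif"], window),
                )
            )
            batches[key] = row["batch_id"]
    return [CloneSet(clones, batch_id=batches[key]) for key, clones in groups.items()]


def write_clones_fasta(path, clone_sets: Sequence[CloneSet], ref: ReferenceSegment) -> None:
    """Clones as aligned FASTA with sample|extraction|pcr|fragment|clone headers."""
    with open(path, "w") as fh:
        for cs in clone_sets:
            for c in cs.clones:
                header = "|".join(
                    [c.sample_id, c.extraction_id, c.pcr_id, str(c.fragment_id), c.clone_id]
                )
                seq = sequence_from_variants(c.haplotype, ref)
                window = get_amplicon(c.fragment_id).window
                segment = seq[window.lo - ref.start : window.hi - ref.start + 1]
                fh.write(f">{header} batch={cs.batch_id}\n{segment}\n")


def read_clones_fasta(path, ref: ReferenceSegment) -> list[CloneSet]:
    from Bio import SeqIO

    groups: dict[tuple, list[CloneRead]] = defaultdict(list)
    batches: dict[tuple, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        fields = record.id.split("|")
        if len(fields) != 5:
            raise ValueError(
                f"clone FASTA header {record.id!r} is not sample|extraction|pcr|fragment|clone"
            )
        sample_id, extraction_id, pcr_id, fragment_s, clone_id = fields
        fragment_id = int(fragment_s)
        window = get_amplicon(fragment_id).window
        # re-embed the fragment into the full reference frame
        seq = list(ref.sequence)
        segment = str(record.seq).upper()
        if len(segment) != len(window):
            raise ValueError(
                f"clone {clone_id}: sequence length {len(segment)} != "
                f"fragment window length {len(window)}"
            )
        seq[window.lo - ref.start : window.hi - ref.start + 1] = segment
        h = variants_from_sequence("".join(seq), ref, window)
        key = (sample_id, extraction_id, pcr_id, fragment_id)
        groups[key].append(
            CloneRead(clone_id, sample_id, extraction_id, pcr_id, fragment_id, h)
        )
        meta = dict(
            part.split("=", 1) for part in record.description.split()[1:] if "=" in part
        )
        batches[key] = meta.get("batch", "batch-1")
    return [CloneSet(clones, batch_id=batches[key]) for key, clones in groups.items()]


# --- database ----------------------------------------------------------------


def write_database_csv(path, db: HaplotypeDatabase) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["individual_id", "population", "motif", "haplogroup"])
        for r in db.records:
            writer.writerow(
                [r.individual_id, r.population_id, format_motif(r.haplotype), r.haplogroup]
            )


def write_population_metadata_csv(path, db: HaplotypeDatabase) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["population", "region", "lat", "lon", "geographic_ok"])
        for population, meta in db.metadata.items():
            writer.writerow(
                [
                    population, meta.region,
                    "" if meta.latitude is None else meta.latitude,
                    "" if meta.longitude is None else meta.longitude,
                    int(meta.geographic_ok),
                ]
            )


def read_database_csv(records_path, metadata_path=None) -> HaplotypeDatabase:
    records = []
    with open(records_path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            records.append(
                DBRecord(
                    individual_id=row["individual_id"],
                    population_id=row["population"],
                    haplotype=parse_motif(row["motif"], COMPLETE_WINDOW),
                    haplogroup=row.get("haplogroup", "") or "",
                )
            )
    metadata: dict[str, PopulationMeta] = {}
    if metadata_path is not None and Path(metadata_path).exists():
        with open(metadata_path, newline="") as fh:
            reader = csv.DictReader(fh)
            for row in reader:
                metadata[row["population"]] = PopulationMeta(
                    region=row.get("region", "") or "",
                    latitude=float(row["lat"]) if row.get("lat") else None,
                    longitude=float(row["lon"]) if row.get("lon") else None,
                    geographic_ok=bool(int(row.get("geographic_ok", "0") or 0)),
                )
    return HaplotypeDatabase(records, metadata)
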