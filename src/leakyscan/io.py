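"""Reading and writing the tabular and sequence formats the tool touches.

Input TIS tables are plain tab-separated text with one row per detected
TIS. The `generic` dialect expects columns gene_id, transcript_id,
position, codon, signal (optional: region, frame, is_single_isoform);
`lee_style` and `ingolia_style` are column-name remappings onto that
schema for tables exported from the two source studies (signal held in
"R_LTM-R_CHX" / "# Harr Reads" respectively). Output TSVs carry a single
'#'-prefixed header line; bedGraph export uses 0-based half-open
intervals covering the 3-nt start codon.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import ContractError, FormatError, ValidationError
from .model import (
    ProbabilityResult,
    Region,
    TisRecord,
    TranscriptTisSet,
    normalize_nucleotides,
)

logger = logging.getLogger(__name__)

_REQUIRED_COLUMNS = ("gene_id", "transcript_id", "position", "codon", "signal")
_OPTIONAL_COLUMNS = ("region", "frame", "is_single_isoform")

#: Column remappings of the study-specific dialects onto the generic schema.
DIALECTS: dict[str, dict[str, str]] = {
    "generic": {},
    "lee_style": {"R_LTM-R_CHX": "signal", "gene": "gene_id", "mRNA": "transcript_id"},
    "ingolia_style": {
        "# Harr Reads": "signal",
        "Gene": "gene_id",
        "Transcript": "transcript_id",
        "Codon": "codon",
        "Init Codon [nt]": "position",
    },
}

_TRUTHY = {"1", "true", "yes", "y"}


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in _TRUTHY


def _read_tsv_with_hash_header(path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise FormatError(f"{path}: empty file")
        columns = header_line.lstrip("#").rstrip("\n").split("\t")
        df = pd.read_csv(
            fh, sep="\t", names=columns, dtype=str, keep_default_na=False
        )
    return df


def read_tis_table(
    path, dialect: str = "generic"
) -> tuple[list[TranscriptTisSet], int]:
    """Read a TIS table into per-transcript 5'->3' ordered sets.

    Rows are grouped by transcript_id and sorted by position; codons are
    uppercased with U mapped to T. Rows that cannot be parsed (bad
    position/signal syntax, wrong field count artifacts) are rejected and
    counted; the count is returned alongside the sets and logged.
    Negative signals and tied positions are *validation* errors, not
    malformed rows: they indicate a broken table, not a stray line.

    Returns
    -------
    (tis_sets, n_rejected)
    """
    if dialect not in DIALECTS:
        raise ContractError(
            f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}"
        )
    df = _read_tsv_with_hash_header(path)
    df = df.rename(columns=DIALECTS[dialect])
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {', '.join(missing)} "
            f"for dialect {dialect!r}"
        )

    n_rejected = 0
    records: list[tuple[str, bool, TisRecord]] = []
    for idx, row in df.iterrows():
        try:
            position = int(row["position"])
            signal = float(row["signal"])
        except (TypeError, ValueError):
            n_rejected += 1
            continue
        if signal < 0:
            raise ValidationError(
                f"{path} row {idx + 2}: negative signal {signal} "
                f"(transcript {row['transcript_id']})"
            )
        region = None
        if "region" in df.columns and row["region"]:
            try:
                region = Region(row["region"])
            except ValueError:
                n_rejected += 1
                continue
        frame = None
        if "frame" in df.columns and row["frame"]:
            try:
                frame = int(row["frame"])
            except ValueError:
                n_rejected += 1
                continue
        single = (
            _parse_bool(row["is_single_isoform"])
            if "is_single_isoform" in df.columns
            else True
        )
        try:
            rec = TisRecord(
                gene_id=str(row["gene_id"]),
                transcript_id=str(row["transcript_id"]),
                position=position,
                codon=str(row["codon"]),
                signal=signal,
                region=region,
                frame=frame,
            )
        except ValidationError:
            n_rejected += 1
            continue
        records.append((rec.transcript_id, single, rec))

    if n_rejected:
        logger.warning("%s: rejected %d malformed row(s)", path, n_rejected)

    by_tx: dict[str, dict] = {}
    for tx_id, single, rec in records:
        entry = by_tx.setdefault(
            tx_id, {"gene_id": rec.gene_id, "single": single, "tis": []}
        )
        entry["tis"].append(rec)
    tis_sets = []
    for tx_id, entry in by_tx.items():
        tis_list = sorted(entry["tis"], key=lambda t: t.position)
        positions = [t.position for t in tis_list]
        if len(set(positions)) != len(positions):
            raise ValidationError(
                f"{path}: transcript {tx_id} reports two TISs at the same "
                "position; scanning order is undefined"
            )
        tis_sets.append(
            TranscriptTisSet(
                transcript_id=tx_id,
                gene_id=entry["gene_id"],
                tis_list=tis_list,
                is_single_isoform=entry["single"],
            )
        )
    tis_sets.sort(key=lambda s: s.transcript_id)
    return tis_sets, n_rejected


def read_transcript_fasta(path) -> dict[str, str]:
    """Read transcript sequences, uppercased with U mapped to T.

    Duplicate record ids and empty files are format errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"{path}: duplicate record id {record.id!r}")
        sequences[record.id] = normalize_nucleotides(str(record.seq))
    if not sequences:
        raise FormatError(f"{path}: no FASTA records found")
    return sequences


def write_tis_table(tis_sets: Sequence[TranscriptTisSet], path) -> None:
    """Write TIS sets back to the generic TSV schema."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "#gene_id\ttranscript_id\tposition\tcodon\tsignal"
            "\tis_single_isoform\n"
        )
        for ts in sorted(tis_sets, key=lambda s: s.transcript_id):
            for t in ts.tis_list:
                fh.write(
                    f"{t.gene_id}\t{t.transcript_id}\t{t.position}\t"
                    f"{t.codon}\t{t.signal:.10g}\t"
                    f"{str(ts.is_single_isoform).lower()}\n"
                )


def write_probability_table(
    results: Sequence[ProbabilityResult],
    tis_sets: Sequence[TranscriptTisSet],
    path,
) -> None:
    """Write per-TIS probabilities as TSV, one row per TIS.

    Rows are ordered deterministically by (transcript_id, position).
    `results` must align 1:1 with `tis_sets`, and each result's
    probability vector with its set's TIS list.
    """
    if len(results) != len(tis_sets):
        raise ContractError(
            f"{len(results)} results vs {len(tis_sets)} TIS sets"
        )
    rows = []
    for result, tis_set in zip(results, tis_sets):
        if result.transcript_id != tis_set.transcript_id:
            raise ContractError(
                f"result for {result.transcript_id} paired with TIS set "
                f"{tis_set.transcript_id}"
            )
        if len(result.probabilities) != len(tis_set):
            raise ContractError(
                f"{result.transcript_id}: {len(result.probabilities)} "
                f"probabilities vs {len(tis_set)} TISs"
            )
        for tis, p in zip(tis_set.tis_list, result.probabilities):
            rows.append(
                (
                    tis.transcript_id,
                    tis.gene_id,
                    tis.position,
                    tis.codon,
                    tis.signal,
                    result.method.value,
                    result.ru,
                    p,
                )
            )
    rows.sort(key=lambda r: (r[0], r[2]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "#transcript_id\tgene_id\tposition\tcodon\tsignal\tmethod"
            "\tru\tprobability\n"
        )
        for tx, gene, pos, codon, signal, method, ru, p in rows:
            fh.write(
                f"{tx}\t{gene}\t{pos}\t{codon}\t{signal:.10g}\t{method}\t"
                f"{ru:.10g}\t{p:.10g}\n"
            )


def read_probability_table(path) -> pd.DataFrame:
    """Read a probability table written by :func:`write_probability_table`."""
    df = _read_tsv_with_hash_header(path)
    for col, typ in (
        ("position", int),
        ("signal", float),
        ("ru", float),
        ("probability", float),
    ):
        df[col] = df[col].astype(typ)
    return df


def export_bedgraph(
    results: Sequence[ProbabilityResult],
    tis_sets: Sequence[TranscriptTisSet],
    path,
    coordinate_map: Optional[Mapping[str, tuple[str, int]]] = None,
    track_name: str = "TIS initiation probability",
) -> None:
    """Export per-TIS probabilities as a bedGraph track.

    Each TIS becomes a 0-based half-open 3-nt interval covering its start
    codon. Without `coordinate_map` the track is in transcript space
    (chrom column = transcript id); with it, each transcript id maps to
    (chromosome, genomic offset of transcript position 0) and intervals
    are shifted accordingly. Identical intervals with conflicting values
    are an error.
    """
    if len(results) != len(tis_sets):
        raise ContractError(
            f"{len(results)} results vs {len(tis_sets)} TIS sets"
        )
    lines: dict[tuple[str, int, int], float] = {}
    for result, tis_set in zip(results, tis_sets):
        for tis, p in zip(tis_set.tis_list, result.probabilities):
            if coordinate_map is not None:
                if tis.transcript_id not in coordinate_map:
                    raise ContractError(
                        f"no coordinate mapping for {tis.transcript_id}"
                    )
                chrom, offset = coordinate_map[tis.transcript_id]
                start = offset + tis.position
            else:
                chrom, start = tis.transcript_id, tis.position
            key = (chrom, start, start + 3)
            if key in lines and lines[key] != p:
                raise ValidationError(
                    f"conflicting probabilities for interval {key}: "
                    f"{lines[key]} vs {p}"
                )
            lines[key] = p
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        for (chrom, start, end), p in sorted(lines.items()):
            fh.write(f"{chrom}\t{start}\t{end}\t{p:.10g}\n")


__all__ = [
    "DIALECTS",
    "export_bedgraph",
    "read_probability_table",
    "read_tis_table",
    "read_transcript_fasta",
    "write_probability_table",
    "write_tis_table",
]
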