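"""Readers and writers: FASTA, BED, silencing-status tables, result tables.

Status tables follow the published survey shape — one row per
(lineage, silenced locus) with a ``Methylated?`` verdict in the
antisense/sense (A/S) notation; diploid reference individuals carry NA.
A bundled example table ships with the package (``bundled_status_table``).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bisulfite_sim import ConvertedObservation
from .methylcall import MethylationCall
from .primer_design import DesignResult
from .snp_diagnostics import DiagnosticSNP, LocusReference

__all__ = [
    "SilencingRecord",
    "parse_status_table",
    "write_status_table",
    "bundled_status_table",
    "tally_status",
    "count_polyploid_lineages",
    "count_methylated_lineages",
    "count_multilocus_silenced",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_locus_reference",
    "observations_from_fasta",
    "observations_to_fasta",
    "snps_to_tsv",
    "calls_to_tsv",
    "primers_to_tsv",
]

_STATUS_TO_TOKEN = {
    "yes_AS": "Yes-A/S",
    "yes_A": "Yes-A",
    "yes_S": "Yes-S",
    "no": "No",
    "na": "NA",
}
_TOKEN_TO_STATUS = {v: k for k, v in _STATUS_TO_TOKEN.items()}
_TOKEN_TO_STATUS[""] = "na"

_COLUMNS = ["Population", "Species", "Lineage", "Locus silenced", "Methylated?"]


@dataclass(frozen=True)
class SilencingRecord:
    """One individual x locus silencing/methylation status row."""

    population: str
    species: str
    lineage_id: str
    locus: str
    silenced_homeolog: str  # d | p | none | genomic_copy_lost
    methylation_status: str  # yes_AS | yes_A | yes_S | no | na


class StatusParseError(ValueError):
    pass


def parse_status_table(source) -> list[SilencingRecord]:
    """Parse a tab-separated silencing-status table.

    ``source`` is a path or open text handle with the header
    ``Population  Species  Lineage  Locus silenced  Methylated?``. Lineage
    tokens are preserved verbatim. A "genomic copy lost" annotation in the
    silenced-locus column maps to ``silenced_homeolog='genomic_copy_lost'``.
    """
    try:
        df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise StatusParseError("empty status table") from exc
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise StatusParseError(f"missing columns: {missing}")
    records = []
    for idx, row in df.iterrows():
        locus_cell = row["Locus silenced"].strip()
        token = row["Methylated?"].strip()
        if token not in _TOKEN_TO_STATUS:
            raise StatusParseError(
                f"row {idx}: unknown methylation status token {token!r}"
            )
        if "genomic copy lost" in locus_cell.lower():
            locus, silenced = "", "genomic_copy_lost"
        elif not locus_cell:
            locus, silenced = "", "none"
        else:
            if "_" not in locus_cell:
                raise StatusParseError(
                    f"row {idx}: cannot parse silenced-locus cell {locus_cell!r}"
                )
            locus, silenced = locus_cell.rsplit("_", 1)
            if silenced not in ("d", "p"):
                raise StatusParseError(
                    f"row {idx}: unknown silenced-homeolog subscript {silenced!r}"
                )
        records.append(
            SilencingRecord(
                population=row["Population"].strip(),
                species=row["Species"].strip(),
                lineage_id=row["Lineage"].strip(),
                locus=locus,
                silenced_homeolog=silenced,
                methylation_status=_TOKEN_TO_STATUS[token],
            )
        )
    if not records:
        raise StatusParseError("status table has no data rows")
    return records


def write_status_table(records: Sequence[SilencingRecord], path) -> None:
    rows = []
    for r in records:
        if r.silenced_homeolog == "genomic_copy_lost":
            cell = "T. pratensis genomic copy lost"
        elif r.silenced_homeolog == "none":
            cell = ""
        else:
            cell = f"{r.locus}_{r.silenced_homeolog}"
        token = "" if r.methylation_status == "na" and cell else _STATUS_TO_TOKEN[r.methylation_status]
        if r.silenced_homeolog == "genomic_copy_lost":
            token = ""
        rows.append([r.population, r.species, r.lineage_id, cell, token])
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def bundled_status_table() -> list[SilencingRecord]:
    """The methylation-survey status table bundled with the package."""
    with resources.files("bsphase.data").joinpath("table1_status.tsv").open() as fh:
        return parse_status_table(fh)


def tally_status(
    records: Iterable[SilencingRecord],
    predicate: Callable[[SilencingRecord], bool],
    mode: str = "lineage",
) -> int:
    """Count rows, or distinct lineages, whose record satisfies ``predicate``."""
    hits = [r for r in records if predicate(r)]
    if mode == "row":
        return len(hits)
    if mode == "lineage":
        return len({r.lineage_id for r in hits})
    raise ValueError(f"unknown tally mode {mode!r}")


def count_polyploid_lineages(records: Iterable[SilencingRecord]) -> int:
    """Distinct allopolyploid (T. miscellus) individuals in the table."""
    return tally_status(records, lambda r: r.species == "T. miscellus")


def count_methylated_lineages(
    records: Iterable[SilencingRecord],
    locus: str,
    homeolog: str,
    populations: set[str] | None = None,
) -> int:
    """Distinct lineages where ``locus`` has its ``homeolog`` methylated."""

    def pred(r: SilencingRecord) -> bool:
        return (
            r.locus == locus
            and r.silenced_homeolog == homeolog
            and r.methylation_status.startswith("yes")
            and (populations is None or r.population in populations)
        )

    return tally_status(records, pred)


def count_multilocus_silenced(records: Iterable[SilencingRecord]) -> int:
    """Distinct lineages with two or more distinct silenced loci."""
    loci: dict[str, set[str]] = {}
    for r in records:
        if r.silenced_homeolog in ("d", "p"):
            loci.setdefault(r.lineage_id, set()).add(r.locus)
    return sum(1 for s in loci.values() if len(s) >= 2)


# ---------------------------------------------------------------------------
# sequence / interval formats


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records.items()],
        str(path),
        "fasta",
    )


def read_bed(path) -> list[tuple[int, int, str]]:
    """BED intervals (0-based half-open), name field = promoter|genic."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"BED line needs chrom/start/end/name: {line!r}")
        start, end, name = int(fields[1]), int(fields[2]), fields[3]
        if start < 0 or end <= start:
            raise ValueError(f"invalid half-open interval [{start}, {end})")
        out.append((start, end, name))
    out.sort()
    for (s1, e1, n1), (s2, e2, n2) in zip(out, out[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping intervals [{s1},{e1}) and [{s2},{e2})")
    return out


def write_bed(regions: Sequence[tuple[int, int, str]], locus_id: str, path) -> None:
    with open(path, "w") as fh:
        for start, end, name in regions:
            fh.write(f"{locus_id}\t{start}\t{end}\t{name}\n")


def read_locus_reference(fasta_path, bed_path=None, locus_id: str | None = None) -> LocusReference:
    """Build a LocusReference from a two-record FASTA (IDs ``<locus>_A``/``<locus>_B``)."""
    seqs = read_fasta(fasta_path)
    a_ids = [i for i in seqs if i.endswith("_A")]
    b_ids = [i for i in seqs if i.endswith("_B")]
    if len(a_ids) != 1 or len(b_ids) != 1:
        raise ValueError("expected exactly one _A and one _B record")
    lid = locus_id or a_ids[0][:-2]
    regions = read_bed(bed_path) if bed_path else []
    return LocusReference(lid, seqs[a_ids[0]], seqs[b_ids[0]], regions)


def observations_to_fasta(observations: Sequence[ConvertedObservation], path) -> None:
    """Record IDs encode ``locus|strand_product|source[|n]``."""
    recs = {}
    counts: dict[str, int] = {}
    for obs in observations:
        base = f"{obs.locus_id}|{obs.strand_product}|{obs.source}"
        if obs.source == "clone":
            counts[base] = counts.get(base, 0) + 1
            base = f"{base}|{counts[base]:02d}"
        recs[base] = obs.seq
    write_fasta(recs, path)


def observations_from_fasta(path) -> list[ConvertedObservation]:
    out = []
    for rid, seq in read_fasta(path).items():
        parts = rid.split("|")
        if len(parts) < 3:
            raise ValueError(f"observation ID {rid!r} not locus|strand_product|source")
        out.append(ConvertedObservation(seq, parts[1], parts[2], parts[0]))
    return out


# ---------------------------------------------------------------------------
# result tables


def snps_to_tsv(snps: Sequence[DiagnosticSNP], locus_id: str, path) -> None:
    rows = [
        [locus_id, s.pos, s.allele_A, s.allele_B, s.status_sense, s.status_antisense]
        for s in snps
    ]
    pd.DataFrame(
        rows,
        columns=["locus", "pos", "allele_A", "allele_B", "status_sense", "status_antisense"],
    ).to_csv(path, sep="\t", index=False)


def calls_to_tsv(calls: Iterable[MethylationCall], locus_id: str, path) -> None:
    rows = [
        [locus_id, c.site.sense_c_pos, c.strand, c.site.region, c.level, c.homeolog, c.evidence]
        for c in calls
    ]
    pd.DataFrame(
        rows, columns=["locus", "site_pos", "strand", "region", "level", "homeolog", "evidence"]
    ).to_csv(path, sep="\t", index=False)


def primers_to_tsv(results: dict[str, DesignResult], locus_id: str, path, top: int = 1) -> None:
    rows = []
    for sp, result in results.items():
        for pset in result.sets[:top]:
            for primer in (pset.outer_F, pset.outer_R, pset.nested_F, pset.nested_R):
                amp = pset.outer_amplicon if "outer" in primer.role else pset.nested_amplicon
                rows.append(
                    [
                        locus_id,
                        primer.role,
                        sp,
                        primer.seq,
                        primer.start,
                        primer.length,
                        amp,
                        round(primer.tm_estimate, 1),
                    ]
                )
    pd.DataFrame(
        rows,
        columns=["locus", "role", "strand_product", "sequence", "start", "length", "amplicon_len", "tm"],
    ).to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    try:
        return asdict(obj)
    except TypeError:
        if isinstance(obj, (set, frozenset)):
            return sorted(obj)
        return str(obj)
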