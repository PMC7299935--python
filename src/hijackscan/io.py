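"""Readers and writers for the pipeline's tabular dialects.

External coordinates are 1-based fully-closed (breakpoint positions,
interaction fragment bounds, ``chrN:start-end`` region strings) and are
converted to the internal 0-based half-open convention on read; writers
convert back, so a read/write round trip preserves external coordinates
exactly. The anchor BED output is 0-based half-open as BED requires.
"""

from __future__ import annotations

import json
import logging
import re
from collections.abc import Iterable, Sequence
from pathlib import Path

import pandas as pd

from .candidates import CandidateGene
from .config import PipelineConfig
from .expression import CountMatrix
from .genome import Breakpoint, GenomicInterval, PromoterInteraction
from .survival import SurvivalRecord

logger = logging.getLogger(__name__)

_REGION_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


class FormatError(ValueError):
    """An input file violates its declared dialect."""


def parse_region(text: str) -> GenomicInterval:
    """Parse a 1-based fully-closed ``chrom:start-end`` string."""
    m = _REGION_RE.match(text.strip())
    if not m:
        raise FormatError(f"malformed region string: {text!r}")
    chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    return GenomicInterval(chrom, start - 1, end)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def _int_at(row, col: str, line_no: int, path) -> int:
    value = row[col]
    try:
        out = int(value)
    except (TypeError, ValueError):
        raise FormatError(
            f"{path}, line {line_no}: non-integer {col} value {value!r}"
        ) from None
    if pd.isna(value):
        raise FormatError(f"{path}, line {line_no}: missing {col}")
    return out


def read_breakpoints(path, format: str = "simple_tsv") -> list[Breakpoint]:
    """Read donor breakpoints; positions are 1-based in the file.

    ``simple_tsv``: columns donor_id, chrom, pos, optional sv_type — one
    breakpoint per row. ``icgc_sv``: columns icgc_donor_id, chr_from,
    chr_from_bkpt, chr_to, chr_to_bkpt, optional variant_type — two
    breakpoints per row (the from- and to-ends of the SV), treated
    independently downstream. Exact duplicates (donor, chrom, pos) are
    deduplicated, first occurrence kept.
    """
    if format not in ("simple_tsv", "icgc_sv"):
        raise ValueError(f"unknown breakpoint format {format!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    bps: list[Breakpoint] = []
    if format == "simple_tsv":
        _require_columns(df, ["donor_id", "chrom", "pos"], path)
        for idx, row in df.iterrows():
            line_no = idx + 2  # header is line 1
            pos = _int_at(row, "pos", line_no, path)
            if pos < 1:
                raise FormatError(f"{path}, line {line_no}: pos must be >= 1")
            bps.append(
                Breakpoint(
                    donor_id=row["donor_id"],
                    chrom=row["chrom"],
                    pos=pos - 1,
                    sv_type=row.get("sv_type") or None,
                )
            )
    else:
        _require_columns(
            df,
            ["icgc_donor_id", "chr_from", "chr_from_bkpt", "chr_to", "chr_to_bkpt"],
            path,
        )
        for idx, row in df.iterrows():
            line_no = idx + 2
            donor = row["icgc_donor_id"]
            sv_type = row.get("variant_type") or None
            from_pos = _int_at(row, "chr_from_bkpt", line_no, path)
            to_pos = _int_at(row, "chr_to_bkpt", line_no, path)
            bps.append(
                Breakpoint(
                    donor_id=donor, chrom=row["chr_from"], pos=from_pos - 1,
                    sv_type=sv_type, mate_chrom=row["chr_to"], mate_pos=to_pos - 1,
                )
            )
            bps.append(
                Breakpoint(
                    donor_id=donor, chrom=row["chr_to"], pos=to_pos - 1,
                    sv_type=sv_type, mate_chrom=row["chr_from"],
                    mate_pos=from_pos - 1,
                )
            )
    seen: set[tuple[str, str, int]] = set()
    unique: list[Breakpoint] = []
    for bp in bps:
        key = (bp.donor_id, bp.chrom, bp.pos)
        if key in seen:
            continue
        seen.add(key)
        unique.append(bp)
    if len(unique) < len(bps):
        logger.info(
            "%s: deduplicated %d repeated breakpoints", path, len(bps) - len(unique)
        )
    return unique


def write_breakpoints(breakpoints: Iterable[Breakpoint], path) -> None:
    rows = [
        {
            "donor_id": bp.donor_id,
            "chrom": bp.chrom,
            "pos": bp.pos + 1,
            "sv_type": bp.sv_type or "",
        }
        for bp in breakpoints
    ]
    pd.DataFrame(rows, columns=["donor_id", "chrom", "pos", "sv_type"]).to_csv(
        path, sep="\t", index=False
    )


def read_interactions(path) -> list[PromoterInteraction]:
    """Read a promoter-interaction table.

    Columns: bait_chr, bait_start, bait_end, pir_chr, pir_start, pir_end,
    gene_ids (semicolon-separated), score; optional interaction_id.
    Coordinates are 1-based fully-closed. Rows without gene annotation are
    dropped (count logged).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(
        df,
        ["bait_chr", "bait_start", "bait_end", "pir_chr", "pir_start",
         "pir_end", "gene_ids", "score"],
        path,
    )
    out: list[PromoterInteraction] = []
    n_dropped = 0
    for idx, row in df.iterrows():
        line_no = idx + 2
        genes = tuple(g for g in row["gene_ids"].split(";") if g)
        if not genes:
            n_dropped += 1
            continue
        coords = {
            c: _int_at(row, c, line_no, path)
            for c in ("bait_start", "bait_end", "pir_start", "pir_end")
        }
        if coords["bait_end"] <= coords["bait_start"]:
            raise FormatError(
                f"{path}, line {line_no}: bait_end <= bait_start"
            )
        if coords["pir_end"] <= coords["pir_start"]:
            raise FormatError(f"{path}, line {line_no}: pir_end <= pir_start")
        try:
            score = float(row["score"])
        except ValueError:
            raise FormatError(
                f"{path}, line {line_no}: non-numeric score {row['score']!r}"
            ) from None
        out.append(
            PromoterInteraction(
                interaction_id=row.get("interaction_id") or f"INT{idx:05d}",
                gene_ids=genes,
                bait=GenomicInterval(
                    row["bait_chr"], coords["bait_start"] - 1, coords["bait_end"]
                ),
                pir=GenomicInterval(
                    row["pir_chr"], coords["pir_start"] - 1, coords["pir_end"]
                ),
                score=score,
            )
        )
    if n_dropped:
        logger.info("%s: dropped %d rows without gene annotation", path, n_dropped)
    return out


def write_interactions(interactions: Iterable[PromoterInteraction], path) -> None:
    rows = [
        {
            "interaction_id": pi.interaction_id,
            "bait_chr": pi.bait.chrom,
            "bait_start": pi.bait.start + 1,
            "bait_end": pi.bait.end,
            "pir_chr": pi.pir.chrom,
            "pir_start": pi.pir.start + 1,
            "pir_end": pi.pir.end,
            "gene_ids": ";".join(pi.gene_ids),
            "score": pi.score,
        }
        for pi in interactions
    ]
    pd.DataFrame(
        rows,
        columns=["interaction_id", "bait_chr", "bait_start", "bait_end",
                 "pir_chr", "pir_start", "pir_end", "gene_ids", "score"],
    ).to_csv(path, sep="\t", index=False)


def read_counts(path) -> CountMatrix:
    """Genes x donors integer count matrix; first column is the gene ID."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicated gene or donor IDs")
    try:
        values = df.astype("int64")
    except (ValueError, TypeError):
        raise FormatError(f"{path}: counts must be integers") from None
    if (values.values < 0).any():
        raise FormatError(f"{path}: counts must be non-negative")
    return CountMatrix(counts=values)


def write_counts(cm: CountMatrix, path) -> None:
    cm.counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_survival(path) -> list[SurvivalRecord]:
    """Columns: donor_id, time, event (0/1), cohort."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["donor_id", "time", "event", "cohort"], path)
    if df["donor_id"].duplicated().any():
        dup = df.loc[df["donor_id"].duplicated(), "donor_id"].tolist()
        raise FormatError(f"{path}: duplicated donor IDs {dup}")
    records: list[SurvivalRecord] = []
    for idx, row in df.iterrows():
        line_no = idx + 2
        try:
            time = float(row["time"])
        except ValueError:
            raise FormatError(
                f"{path}, line {line_no}: non-numeric time {row['time']!r}"
            ) from None
        if time < 0:
            raise FormatError(f"{path}, line {line_no}: negative time")
        if row["event"] not in ("0", "1"):
            raise FormatError(
                f"{path}, line {line_no}: event must be 0 or 1, "
                f"got {row['event']!r}"
            )
        records.append(
            SurvivalRecord(
                donor_id=row["donor_id"], time=time,
                event=row["event"] == "1", cohort=row["cohort"],
            )
        )
    return records


def write_survival(records: Iterable[SurvivalRecord], path) -> None:
    rows = [
        {
            "donor_id": r.donor_id,
            "time": r.time,
            "event": int(r.event),
            "cohort": r.cohort,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["donor_id", "time", "event", "cohort"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_sets(path) -> dict[str, list[str]]:
    """Gene sets: GMT (name, description, members...) for ``.gmt`` files,
    otherwise one gene ID per line under the file's stem name."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        if path.suffix.lower() == ".gmt":
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 3:
                    sets[parts[0]] = [g for g in parts[2:] if g]
        else:
            genes = [line.strip() for line in fh if line.strip()]
            sets[path.stem] = genes
    return sets


def write_candidates(
    candidates: Sequence[CandidateGene],
    prefix,
    config: PipelineConfig | None = None,
    stage_counts: dict | None = None,
) -> dict[str, Path]:
    """Write the candidate table (TSV), disrupted-anchor BED, and a JSON run
    summary under ``<prefix>.tsv`` / ``<prefix>_anchors.bed`` /
    ``<prefix>_summary.json``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv_path = prefix.with_suffix(".tsv")
    bed_path = prefix.parent / f"{prefix.name}_anchors.bed"
    json_path = prefix.parent / f"{prefix.name}_summary.json"

    rows = []
    for cand in candidates:
        res = cand.survival
        rows.append(
            {
                "gene_id": cand.gene_id,
                "p_value_os": res.p if res else "",
                "padj_os": res.padj if res else "",
                "gene_locus": (
                    cand.gene_locus.region_string() if cand.gene_locus else ""
                ),
                "disrupted_pir_anchors": ";".join(
                    sorted(a.region_string() for a in cand.anchors)
                ),
                "n_donors": cand.n_donors,
            }
        )
    pd.DataFrame(
        rows,
        columns=["gene_id", "p_value_os", "padj_os", "gene_locus",
                 "disrupted_pir_anchors", "n_donors"],
    ).to_csv(tsv_path, sep="\t", index=False)

    with open(bed_path, "w") as fh:
        seen = set()
        for cand in candidates:
            for a in sorted(cand.anchors):
                key = (a.chrom, a.start, a.end, cand.gene_id)
                if key in seen:
                    continue
                seen.add(key)
                fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{cand.gene_id}\n")

    summary = {
        "n_candidates": len(candidates),
        "stage_counts": stage_counts or {},
    }
    if config is not None:
        summary["config"] = config.to_dict()
        summary["config_hash"] = config.config_hash()
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2)
    return {"tsv": tsv_path, "bed": bed_path, "summary": json_path}
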