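"""Format handlers: FASTA, BED6, refFlat/genePred, TSV tables, YAML config.

All readers are gzip-transparent (by ``.gz`` suffix) and all coordinates stay
0-based half-open; writers round-trip semantically (coordinates, strands,
scores survive a write/read cycle).
"""
from __future__ import annotations

import gzip
import hashlib
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import ExpressionMatrix
from .features import ESTRecord, GeneModel
from .mutations import MutationRecord
from .scan import PG4Hit


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    """Multi-record FASTA -> {name: sequence}; headers cut at first whitespace."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------- BED6 hits

def write_hits_bed(hits: Sequence[PG4Hit], path) -> None:
    """BED6: name = pG4 running index, score = q_score (0 when absent)."""
    with _open_text(path, "wt") as fh:
        for i, h in enumerate(hits):
            score = h.q_score if h.q_score is not None else 0
            fh.write(f"{h.chrom}\t{h.start}\t{h.end}\tpG4_{i}\t{score}\t{h.strand}\n")


def read_hits_bed(path) -> list[PG4Hit]:
    """Read BED6 hits; run decomposition is not stored in BED (see the TSV)."""
    hits: list[PG4Hit] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 BED columns")
            chrom, start, end, _name, score, strand = parts[:6]
            q = float(score)
            hits.append(PG4Hit(
                chrom=chrom, start=int(start), end=int(end), strand=strand,
                n_runs=0, sequence="", q_score=q if q != 0 else None,
            ))
    return hits


def write_hits_decomposition(hits: Sequence[PG4Hit], path) -> None:
    """TSV with the run/loop decomposition of each hit."""
    rows = []
    for i, h in enumerate(hits):
        rows.append({
            "name": f"pG4_{i}", "chrom": h.chrom, "start": h.start, "end": h.end,
            "strand": h.strand, "n_runs": h.n_runs,
            "runs": ";".join(f"{s}-{e}" for s, e in h.runs),
            "loops": ";".join(h.loops),
            "sequence": h.sequence,
            "q_score": "" if h.q_score is None else h.q_score,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- gene models

def read_gene_models(path) -> list[GeneModel]:
    """refFlat (11 col, leading gene symbol) or genePred (10 col) TSV.

    Handles the UCSC dialect of comma-terminated exon lists. The gene id is
    the refFlat gene symbol when present, else the transcript name.
    """
    models: list[GeneModel] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) >= 11 and f[3] in "+-":
                gene_id, _name, chrom, strand = f[0], f[1], f[2], f[3]
                rest = f[4:11]
            elif len(f) >= 10 and f[2] in "+-":
                gene_id, chrom, strand = f[0], f[1], f[2]
                rest = f[3:10]
            else:
                raise ValueError(f"{path}:{lineno}: not a refFlat/genePred row")
            tx_start, tx_end, cds_start, cds_end, _n_exons = (int(x) for x in rest[:5])
            exon_starts = tuple(int(x) for x in rest[5].rstrip(",").split(","))
            exon_ends = tuple(int(x) for x in rest[6].rstrip(",").split(","))
            models.append(GeneModel(
                gene_id=gene_id, chrom=chrom, strand=strand,
                tx_start=tx_start, tx_end=tx_end,
                cds_start=cds_start, cds_end=cds_end,
                exon_starts=exon_starts, exon_ends=exon_ends,
            ))
    return models


def write_gene_models(models: Iterable[GeneModel], path) -> None:
    """refFlat dialect (gene symbol + transcript name, trailing-comma lists)."""
    with _open_text(path, "wt") as fh:
        for m in models:
            starts = ",".join(str(s) for s in m.exon_starts) + ","
            ends = ",".join(str(e) for e in m.exon_ends) + ","
            fh.write("\t".join(str(x) for x in (
                m.gene_id, m.gene_id, m.chrom, m.strand, m.tx_start, m.tx_end,
                m.cds_start, m.cds_end, len(m.exon_starts), starts, ends,
            )) + "\n")


# ---------------------------------------------------------------- ESTs

def read_ests(path) -> list[ESTRecord]:
    """EST start records.

    Accepts a simple 3-column TSV (chrom, strand, position; header optional)
    or UCSC all_est-style PSL rows with a leading bin column, where the
    strand-aware 5' end is tStart on + and tEnd-1 on -.
    """
    ests: list[ESTRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) >= 18:  # bin + PSL
                strand = f[9]
                chrom = f[14]
                pos = int(f[16]) if strand == "+" else int(f[17]) - 1
            elif len(f) >= 3:
                chrom, strand = f[0], f[1]
                if lineno == 1 and not f[2].lstrip("-").isdigit():
                    continue  # header
                pos = int(f[2])
            else:
                raise ValueError(f"{path}:{lineno}: not an EST record")
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            ests.append(ESTRecord(chrom=chrom, strand=strand, start_site=pos))
    return ests


def write_ests(ests: Iterable[ESTRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("chrom\tstrand\tposition\n")
        for e in ests:
            fh.write(f"{e.chrom}\t{e.strand}\t{e.start_site}\n")


# ---------------------------------------------------------------- expression

def write_expression(m: ExpressionMatrix, matrix_path, meta_path) -> None:
    m.values.rename_axis("gene").to_csv(matrix_path, sep="\t")
    m.sample_meta.rename_axis("sample").to_csv(meta_path, sep="\t")


def read_expression(matrix_path, meta_path) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return ExpressionMatrix(values, meta)


# ---------------------------------------------------------------- mutations

_MUT_COLUMNS = ["chrom", "pos", "ref", "alt", "mut_type", "source", "label", "sample_id"]


def write_mutations(muts: Iterable[MutationRecord], path) -> None:
    rows = [
        {c: getattr(m, c) for c in _MUT_COLUMNS}
        for m in muts
    ]
    pd.DataFrame(rows, columns=_MUT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_mutations(path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str, "sample_id": str},
                     keep_default_na=False)
    return [
        MutationRecord(
            chrom=str(r.chrom), pos=int(r.pos), ref=r.ref, alt=r.alt,
            mut_type=r.mut_type, source=r.source, label=str(r.label),
            sample_id=str(r.sample_id),
        )
        for r in df.itertuples()
    ]


def read_cosmic_mutations(path, source: str = "somatic") -> list[MutationRecord]:
    """COSMIC-style export: 1-based inclusive "chrom:start-end" positions,
    sample name, primary site; CDS/AA syntax is ignored."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    cols = {c.lower().replace(" ", "_"): c for c in df.columns}

    def col(*names):
        for n in names:
            if n in cols:
                return cols[n]
        raise ValueError(f"COSMIC table lacks any of columns {names}")

    pos_c = col("mutation_genome_position", "genome_position")
    sample_c = col("sample_name", "sample")
    site_c = col("primary_site", "site")
    desc_c = col("mutation_description", "description")
    out: list[MutationRecord] = []
    for r in df.itertuples(index=False):
        row = dict(zip(df.columns, r))
        loc = str(row[pos_c])
        chrom, span = loc.split(":")
        start_1, _end = span.split("-")
        desc = str(row[desc_c]).lower()
        if "deletion" in desc:
            mut_type = "deletion"
        elif "insertion" in desc:
            mut_type = "insertion"
        elif "duplication" in desc:
            mut_type = "duplication"
        else:
            mut_type = "substitution"
        chrom_name = chrom if chrom.startswith("chr") else f"chr{chrom}"
        out.append(MutationRecord(
            chrom=chrom_name, pos=int(start_1) - 1, ref="N", alt="",
            mut_type=mut_type, source=source, label=str(row[site_c]),
            sample_id=str(row[sample_c]),
        ))
    return out


# ---------------------------------------------------------------- config / misc

def read_yaml(path) -> dict:
    with _open_text(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj, path) -> None:
    with _open_text(path, "wt") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
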