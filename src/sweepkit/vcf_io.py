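"""Reading and writing the standard formats the pipeline touches.

VCF is handled through :mod:`pysam` (htslib); BED4 and GFF3 gene intervals are
parsed with pandas.  All internal coordinates are 0-based half-open: VCF
(1-based) and GFF (1-based inclusive) are converted at this boundary and
nowhere else.

Only biallelic records are used downstream; multiallelic records are skipped
(with a logged count) by default, or split into per-alt biallelic records on
request.  INFO metrics that are absent stay absent — they are never silently
treated as zero, so the hard filters can be conservative about them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import pysam

from .simulate import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

INFO_KEYS = ("QD", "DP", "FS", "MQ", "SOR")

__all__ = [
    "VariantRecord",
    "GeneInterval",
    "read_vcf",
    "write_vcf",
    "records_to_matrix",
    "matrix_to_records",
    "read_intervals",
    "stream_fastq_kmers",
    "write_histogram_tsv",
    "read_histogram_tsv",
]


@dataclass
class VariantRecord:
    """One biallelic VCF record with the quality annotations the filters use."""

    chrom: str
    pos: int  # 1-based
    id: str | None
    ref: str
    alt: str
    qual: float | None
    info: dict[str, float]  # QD/DP/FS/MQ/SOR where present
    filter_status: list[str] = field(default_factory=list)  # empty/["PASS"] = pass
    genotypes: list[int | None] = field(default_factory=list)  # alt-allele counts

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based, must be >= 1")
        if self.qual is not None and self.qual < 0:
            raise ValueError("qual must be >= 0 or missing")

    @property
    def passes(self) -> bool:
        return self.filter_status in ([], ["PASS"])


@dataclass(frozen=True)
class GeneInterval:
    """A gene on 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    gene_id: str
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval for {self.gene_id}")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    multiallelic: str = "skip",
    snps_only: bool = True,
) -> tuple[list[VariantRecord], list[str]]:
    """Parse a VCF into :class:`VariantRecord` objects plus the sample list.

    ``multiallelic``: "skip" (default, logged count) or "split" into one
    biallelic record per alt allele (genotypes recoded against that alt).
    ``snps_only`` drops indels and symbolic alleles.
    """
    if multiallelic not in ("skip", "split"):
        raise ValueError("multiallelic must be 'skip' or 'split'")
    records: list[VariantRecord] = []
    n_multi = n_nonsnp = 0
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) == 0:
                continue
            if len(alts) > 1:
                n_multi += 1
                if multiallelic == "skip":
                    continue
            take = range(len(alts)) if len(alts) > 1 else (0,)
            for ai in take:
                alt = alts[ai]
                if snps_only and (len(rec.ref) != 1 or len(alt) != 1 or not alt.isalpha()):
                    n_nonsnp += 1
                    continue
                info: dict[str, float] = {}
                for key in INFO_KEYS:
                    if key in rec.info:
                        val = rec.info[key]
                        if isinstance(val, tuple):
                            val = val[0]
                        info[key] = float(val)
                genotypes: list[int | None] = []
                for s in samples:
                    gt = rec.samples[s].get("GT", (None,))
                    if gt is None or any(a is None for a in gt):
                        genotypes.append(None)
                    else:
                        genotypes.append(sum(1 for a in gt if a == ai + 1))
                filt = list(rec.filter.keys())
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        id=rec.id,
                        ref=rec.ref,
                        alt=alt,
                        qual=None if rec.qual is None else float(rec.qual),
                        info=info,
                        filter_status=filt,
                        genotypes=genotypes,
                    )
                )
    if n_multi:
        verb = "split" if multiallelic == "split" else "skipped"
        logger.info("%d multiallelic records %s", n_multi, verb)
    if n_nonsnp:
        logger.info("%d non-SNP alleles dropped", n_nonsnp)
    return records, samples


def _build_header(
    samples: list[str], contigs: Iterable[str], filters: Iterable[str]
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for c in contigs:
        header.contigs.add(c)
    header.info.add("QD", 1, "Float", "Variant confidence normalized by depth")
    header.info.add("DP", 1, "Integer", "Combined read depth")
    header.info.add("FS", 1, "Float", "Phred-scaled Fisher strand-bias p-value")
    header.info.add("MQ", 1, "Float", "RMS mapping quality")
    header.info.add("SOR", 1, "Float", "Symmetric strand odds ratio")
    header.formats.add("GT", 1, "String", "Genotype")
    for name in filters:
        if name != "PASS":
            header.filters.add(name, None, None, f"Failed {name} hard filter")
    for s in samples:
        header.add_sample(s)
    return header


def write_vcf(
    records: list[VariantRecord], samples: list[str], path: str | Path
) -> None:
    """Write VCFv4.2; FILTER carries PASS or the failed-filter names."""
    keys = [(r.chrom, r.pos) for r in records]
    if any(k2 < k1 for k1, k2 in zip(keys, keys[1:])):
        raise ValueError("records must be sorted by (chrom, pos)")
    contigs: dict[str, None] = {}
    filters: dict[str, None] = {}
    for r in records:
        contigs.setdefault(r.chrom, None)
        for f in r.filter_status:
            filters.setdefault(f, None)
    header = _build_header(samples, contigs, filters)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in records:
            rec = out.new_record(
                contig=r.chrom,
                start=r.pos - 1,
                stop=r.pos,
                alleles=(r.ref, r.alt),
                id=r.id,
                qual=r.qual,
            )
            for key, val in r.info.items():
                rec.info[key] = int(val) if key == "DP" else val
            if r.filter_status:
                for f in r.filter_status:
                    rec.filter.add(f)
            else:
                rec.filter.add("PASS")
            for s, g in zip(samples, r.genotypes):
                if g is None:
                    rec.samples[s]["GT"] = (None, None)
                else:
                    rec.samples[s]["GT"] = (0, 0) if g == 0 else ((0, 1) if g == 1 else (1, 1))
            out.write(rec)


def records_to_matrix(
    records: list[VariantRecord],
    samples: list[str],
    pop_labels: list[str],
) -> GenotypeMatrix:
    """Assemble sorted biallelic records into a :class:`GenotypeMatrix`."""
    if not records:
        raise ValueError("no records")
    calls = np.full((len(samples), len(records)), MISSING, dtype=np.int8)
    for j, rec in enumerate(records):
        for i, g in enumerate(rec.genotypes):
            if g is not None:
                calls[i, j] = g
    return GenotypeMatrix(
        sample_ids=list(samples),
        pop_labels=list(pop_labels),
        chrom=np.array([r.chrom for r in records], dtype=object),
        pos=np.array([r.pos for r in records], dtype=np.int64),
        ref=np.array([r.ref for r in records], dtype=object),
        alt=np.array([r.alt for r in records], dtype=object),
        calls=calls,
    )


def matrix_to_records(matrix: GenotypeMatrix) -> list[VariantRecord]:
    records = []
    for j in range(matrix.n_sites):
        genotypes = [
            None if c == MISSING else int(c) for c in matrix.calls[:, j]
        ]
        records.append(
            VariantRecord(
                chrom=str(matrix.chrom[j]),
                pos=int(matrix.pos[j]),
                id=None,
                ref=str(matrix.ref[j]),
                alt=str(matrix.alt[j]),
                qual=None,
                info={},
                genotypes=genotypes,
            )
        )
    return records


# ---------------------------------------------------------------------------
# gene intervals
# ---------------------------------------------------------------------------

def read_intervals(
    path: str | Path, fmt: str | None = None, feature_type: str = "gene"
) -> list[GeneInterval]:
    """Read gene intervals from BED4 (verbatim) or GFF3 (start shifted by -1).

    GFF keeps only rows of ``feature_type`` and takes the gene id from the
    ``ID=`` attribute.  Records with start >= end are rejected with a warning.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.name.lower()
        if suffix.endswith((".bed", ".bed.gz")):
            fmt = "bed"
        elif suffix.endswith((".gff", ".gff3", ".gff.gz", ".gff3.gz")):
            fmt = "gff"
        else:
            raise ValueError(f"cannot infer interval format from {path.name}")
    if fmt not in ("bed", "gff"):
        raise ValueError("format must be 'bed' or 'gff'")

    intervals: list[GeneInterval] = []
    if fmt == "bed":
        df = pd.read_csv(
            path, sep=r"\s+", comment="#", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
            engine="python",
        )
        for row in df.itertuples(index=False):
            start, end = int(row.start), int(row.end)
            strand = row.strand if isinstance(row.strand, str) else "."
            name = row.name if isinstance(row.name, str) else f"{row.chrom}:{start}-{end}"
            if start >= end:
                logger.warning("dropping empty BED interval %s:%d-%d", row.chrom, start, end)
                continue
            intervals.append(GeneInterval(str(row.chrom), start, end, name, strand))
    else:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "source", "type", "start", "end",
                   "score", "strand", "phase", "attributes"],
        )
        df = df[df["type"] == feature_type]
        for row in df.itertuples(index=False):
            start, end = int(row.start) - 1, int(row.end)  # GFF 1-based inclusive
            if start >= end:
                logger.warning("dropping empty GFF interval %s:%d-%d", row.chrom, start, end)
                continue
            gene_id = None
            for fieldpart in str(row.attributes).split(";"):
                key, _, val = fieldpart.strip().partition("=")
                if key == "ID":
                    gene_id = val
                    break
            if gene_id is None:
                gene_id = f"{row.chrom}:{start}-{end}"
            intervals.append(GeneInterval(str(row.chrom), start, end, gene_id, str(row.strand)))
    return intervals


# ---------------------------------------------------------------------------
# FASTQ k-mer streaming
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _canonical(kmer: str) -> str:
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


def stream_fastq_kmers(path: str | Path, k: int):
    """Count canonical k-mers in a (possibly gzipped) FASTQ into a spectrum.

    Canonical = lexicographic min of a k-mer and its reverse complement, so a
    read and its reverse complement contribute identically.  K-mers containing
    non-ACGT characters are skipped; reads shorter than k contribute no k-mers
    but still count toward ``n_base``.
    """
    from collections import Counter

    from .kmer import KmerSpectrum

    if not 1 < k <= 31:
        raise ValueError("k must be in (1, 31]")
    counts: Counter[str] = Counter()
    n_base = 0
    read_lens: Counter[int] = Counter()
    n_skipped = 0
    with pysam.FastxFile(str(path)) as fq:
        for read in fq:
            seq = read.sequence.upper()
            n_base += len(seq)
            read_lens[len(seq)] += 1
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if any(c not in "ACGT" for c in kmer):
                    n_skipped += 1
                    continue
                counts[_canonical(kmer)] += 1
    if not read_lens:
        raise ValueError(f"no reads in {path}")
    if n_skipped:
        logger.info("%d k-mer positions skipped (non-ACGT)", n_skipped)
    modal_len = max(read_lens, key=lambda l: (read_lens[l], l))
    depth_hist: Counter[int] = Counter(counts.values())
    return KmerSpectrum(
        k=k,
        read_len=modal_len,
        n_base=n_base,
        histogram=dict(depth_hist),
    )


# ---------------------------------------------------------------------------
# histogram TSV
# ---------------------------------------------------------------------------

def write_histogram_tsv(spectrum, path: str | Path) -> None:
    """Two-column depth/count TSV with header comments recording k, L, n_base."""
    with open(path, "w") as fh:
        fh.write(f"#k={spectrum.k}\n#L={spectrum.read_len}\n#n_base={spectrum.n_base}\n")
        fh.write("depth\tcount\n")
        for depth in sorted(spectrum.histogram):
            fh.write(f"{depth}\t{spectrum.histogram[depth]}\n")


def read_histogram_tsv(path: str | Path):
    from .kmer import KmerSpectrum

    meta: dict[str, int] = {}
    hist: dict[int, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key] = int(val)
            elif not line[0].isdigit():
                continue  # column header
            else:
                depth, count = line.split("\t")
                hist[int(depth)] = int(count)
    for key in ("k", "L", "n_base"):
        if key not in meta:
            raise ValueError(f"histogram TSV missing #{key}= header")
    return KmerSpectrum(k=meta["k"], read_len=meta["L"], n_base=meta["n_base"], histogram=hist)
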