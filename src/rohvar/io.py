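"""Readers and writers for the standard formats the pipeline touches.

VCF v4.2 through pysam, FASTA through Biopython, GFF3 through gffutils;
PED/MAP/FAM and the small TSV tables are plain-text tables written and read
directly (no dedicated library for these dialects is available in the
stack). Internally every coordinate is 0-based half-open; VCF/GFF3 are
1-based inclusive and BED is 0-based half-open, and conversion happens
exactly once, here.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genotype_model import MISSING
from .roh import GenotypeMatrix, MarkerMap, ROHRegion
from .simdata import Individual, Pedigree
from .splice import TranscriptModel
from .variant_filter import VariantRecord

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_fasta",
    "write_fasta",
    "read_gff3_subset",
    "write_gff3",
    "write_ped_map",
    "read_ped_map",
    "write_fam",
    "read_fam",
    "write_bed",
    "read_bed_regions",
    "write_regions_tsv",
    "write_known_tsv",
    "read_known_tsv",
    "write_genotype_tsv",
    "read_genotype_tsv",
]


class ParseError(ValueError):
    pass


_GT_TO_TUPLE = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}


def write_vcf(
    path: str | Path,
    variants: Sequence[VariantRecord],
    contigs: Optional[dict[str, int]] = None,
    quals: Optional[dict[tuple[str, int], float]] = None,
) -> None:
    """Write biallelic records with GT fields as uncompressed VCF v4.2.

    ``quals`` optionally maps (chrom, pos) to a QUAL value (the genotype
    caller stores a phred-scaled mean posterior there).
    """
    samples: list[str] = []
    for v in variants:
        for s in v.genotypes:
            if s not in samples:
                samples.append(s)
    header = pysam.VariantHeader()
    if contigs is None:
        contigs = {}
        for v in variants:
            contigs[v.chrom] = max(contigs.get(v.chrom, 0), v.pos + 1)
    for name, length in contigs.items():
        header.add_line(f"##contig=<ID={name},length={length}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda x: (x.chrom, x.pos)):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt), id=v.vid
            )
            if quals is not None and (v.chrom, v.pos) in quals:
                rec.qual = quals[(v.chrom, v.pos)]
            for s in samples:
                rec.samples[s]["GT"] = _GT_TO_TUPLE[v.genotypes.get(s, MISSING)]
            out.write(rec)


def _vcf_line_diagnosis(path: Path, exc: Exception) -> ParseError:
    """Best-effort localisation of the malformed line for the error message."""
    try:
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                if line.startswith("#"):
                    continue
                if line.count("\t") < 7 or not line.endswith("\n"):
                    return ParseError(f"{path}: malformed VCF record at line {i}: {exc}")
    except OSError:
        pass
    return ParseError(f"{path}: malformed VCF: {exc}")


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read biallelic records with GT fields; './.' maps to the missing code."""
    path = Path(path)
    variants = []
    try:
        with pysam.VariantFile(str(path)) as vf:
            samples = list(vf.header.samples)
            for rec in vf:
                if rec.alts is None or len(rec.alts) != 1:
                    raise ParseError(
                        f"{path}: record {rec.contig}:{rec.pos} is not biallelic"
                    )
                geno = {}
                for s in samples:
                    gt = rec.samples[s].get("GT")
                    if gt is None or None in gt:
                        geno[s] = MISSING
                    else:
                        geno[s] = int(sum(gt))
                variants.append(
                    VariantRecord(
                        chrom=rec.contig,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=rec.alts[0],
                        genotypes=geno,
                        vid=rec.id or ".",
                    )
                )
    except ParseError:
        raise
    except Exception as exc:
        raise _vcf_line_diagnosis(path, exc) from exc
    return variants


# -- FASTA -----------------------------------------------------------------


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# -- GFF3 subset -----------------------------------------------------------


def write_gff3(path: str | Path, transcripts: Sequence[TranscriptModel]) -> None:
    """gene/mRNA/exon/CDS lines, 1-based inclusive coordinates."""
    lines = ["##gff-version 3"]
    for tr in transcripts:
        lo, hi = tr.gene_span
        gene_id = tr.id.rsplit(".", 1)[0]
        lines.append(
            "\t".join(
                [tr.chrom, "rohvar", "gene", str(lo + 1), str(hi), ".", tr.strand, ".",
                 f"ID={gene_id}"]
            )
        )
        lines.append(
            "\t".join(
                [tr.chrom, "rohvar", "mRNA", str(lo + 1), str(hi), ".", tr.strand, ".",
                 f"ID={tr.id};Parent={gene_id}"]
            )
        )
        offs = tr.exon_t_offsets()
        for i, (s, e) in enumerate(tr.exons):
            lines.append(
                "\t".join(
                    [tr.chrom, "rohvar", "exon", str(s + 1), str(e), ".", tr.strand, ".",
                     f"ID={tr.id}.exon{i + 1};Parent={tr.id}"]
                )
            )
            # CDS portion of this exon, in transcript coords
            t0, t1 = offs[i], offs[i] + (e - s)
            c0, c1 = max(t0, tr.cds_start), min(t1, tr.cds_end)
            if c0 < c1:
                if tr.strand == "+":
                    g0, g1 = s + (c0 - t0), s + (c1 - t0)
                else:
                    g1, g0 = e - (c0 - t0), e - (c1 - t0)
                phase = (3 - (c0 - tr.cds_start) % 3) % 3
                lines.append(
                    "\t".join(
                        [tr.chrom, "rohvar", "CDS", str(g0 + 1), str(g1), ".", tr.strand,
                         str(phase), f"ID={tr.id}.cds;Parent={tr.id}"]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3_subset(path: str | Path, genome: dict[str, str]) -> list[TranscriptModel]:
    """Reconstruct transcript models from a gene/mRNA/exon/CDS GFF3 subset.

    Exons are validated against the chromosome sequence lengths; the spliced
    sequence is assembled from the genome.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    transcripts = []
    for mrna in db.features_of_type("mRNA"):
        exons = list(db.children(mrna, featuretype="exon", order_by="start"))
        cds_parts = list(db.children(mrna, featuretype="CDS", order_by="start"))
        if not exons or not cds_parts:
            raise ParseError(f"{path}: mRNA {mrna.id} lacks exon/CDS children")
        chrom = mrna.seqid
        if chrom not in genome:
            raise ParseError(f"{path}: unknown chromosome {chrom!r}")
        clen = len(genome[chrom])
        for ex in exons:
            if ex.end > clen or ex.start < 1:
                raise ParseError(
                    f"{path}: exon {ex.start}-{ex.end} of {mrna.id} outside "
                    f"chromosome {chrom} (length {clen})"
                )
        strand = mrna.strand
        ivs = [(ex.start - 1, ex.end) for ex in exons]
        if strand == "-":
            ivs = ivs[::-1]
        pieces = []
        for s, e in ivs:
            seg = genome[chrom][s:e]
            pieces.append(seg if strand == "+" else str(Seq(seg).reverse_complement()))
        seq = "".join(pieces)
        # CDS genomic extremes -> transcript coords
        cds_lo = min(c.start - 1 for c in cds_parts)
        cds_hi = max(c.end for c in cds_parts)
        model = TranscriptModel(
            id=mrna.id, chrom=chrom, strand=strand, exons=tuple(ivs),
            cds_start=0, cds_end=len(seq), seq=seq,
        )
        g_first = cds_lo if strand == "+" else cds_hi - 1
        g_last = cds_hi - 1 if strand == "+" else cds_lo
        t_first, t_last = model.g_to_t(g_first), model.g_to_t(g_last)
        if t_first is None or t_last is None:
            raise ParseError(f"{path}: CDS bounds of {mrna.id} fall outside exons")
        transcripts.append(
            TranscriptModel(
                id=mrna.id, chrom=chrom, strand=strand, exons=tuple(ivs),
                cds_start=t_first, cds_end=t_last + 1, seq=seq,
            )
        )
    transcripts.sort(key=lambda t: t.id)
    return transcripts


# -- PED/MAP ---------------------------------------------------------------

_PED_ALLELES = {0: "A A", 1: "A B", 2: "B B", MISSING: "0 0"}


def write_ped_map(
    prefix: str | Path, matrix: GenotypeMatrix, pedigree: Optional[Pedigree] = None
) -> tuple[Path, Path]:
    """Write PLINK-style .ped/.map text files (alleles A=ref, B=alt)."""
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for row in matrix.markers.table.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.id}\t0\t{row.pos + 1}\n")
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(matrix.samples):
            sire = dam = "0"
            sex, pheno = "0", "0"
            if pedigree is not None:
                ind = pedigree.by_id(sample)
                sire, dam = ind.sire or "0", ind.dam or "0"
                sex = "1" if ind.sex == "M" else "2"
                pheno = "2" if ind.role == "case" else "1"
            alleles = " ".join(_PED_ALLELES[int(g)] for g in matrix.geno[i])
            fh.write(f"FAM1 {sample} {sire} {dam} {sex} {pheno} {alleles}\n")
    return ped_path, map_path


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    rows = []
    with open(map_path) as fh:
        for line in fh:
            chrom, mid, _, pos1 = line.split()
            rows.append((chrom, int(pos1) - 1, mid))
    mmap = MarkerMap(pd.DataFrame(rows, columns=["chrom", "pos", "id"]))
    decode = {("A", "A"): 0, ("A", "B"): 1, ("B", "A"): 1, ("B", "B"): 2, ("0", "0"): MISSING}
    samples, genos = [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if len(fields) != 6 + 2 * len(mmap):
                raise ParseError(
                    f"{ped_path}: line {ln}: expected {6 + 2 * len(mmap)} fields "
                    f"(marker count mismatch with {map_path}), got {len(fields)}"
                )
            samples.append(fields[1])
            pairs = zip(fields[6::2], fields[7::2])
            genos.append([decode[p] for p in pairs])
    return GenotypeMatrix(
        samples=tuple(samples), markers=mmap, geno=np.array(genos, dtype=np.int8)
    )


def write_genotype_tsv(path: str | Path, matrix: GenotypeMatrix) -> None:
    """Genotype matrix as TSV: markers as rows, samples as columns."""
    df = matrix.markers.table.copy()
    for i, s in enumerate(matrix.samples):
        df[s] = matrix.geno[i]
    df.to_csv(path, sep="\t", index=False)


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta = ["chrom", "pos", "id"]
    samples = [c for c in df.columns if c not in meta]
    return GenotypeMatrix(
        samples=tuple(samples),
        markers=MarkerMap(df[meta].copy()),
        geno=df[samples].to_numpy().T.astype(np.int8),
    )


# -- FAM-style pedigree TSV -------------------------------------------------


def write_fam(path: str | Path, pedigree: Pedigree) -> None:
    with open(path, "w") as fh:
        fh.write("id\tsire\tdam\tsex\trole\n")
        for ind in pedigree:
            fh.write(
                f"{ind.id}\t{ind.sire or '0'}\t{ind.dam or '0'}\t{ind.sex}\t{ind.role}\n"
            )


def read_fam(path: str | Path) -> Pedigree:
    """Pedigree structure and roles; causal genotypes are unknown (-1)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"id", "sire", "dam", "sex", "role"}
    if not need <= set(df.columns):
        raise ParseError(f"{path}: FAM-style TSV needs columns {sorted(need)}")
    inds = [
        Individual(
            id=r.id,
            sire=None if r.sire == "0" else r.sire,
            dam=None if r.dam == "0" else r.dam,
            sex=r.sex,
            role=r.role,
            causal_gt=-1,
            generation=-1,
        )
        for r in df.itertuples(index=False)
    ]
    return Pedigree(inds)


# -- BED / region reports ---------------------------------------------------


def write_bed(path: str | Path, regions: Sequence[ROHRegion]) -> None:
    """0-based half-open BED with the priority as the score column."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions, 1):
            score = "." if r.priority is None else f"{r.priority:.4f}"
            fh.write(f"{r.chrom}\t{r.start_bp}\t{r.end_bp}\tROH{i}\t{score}\n")


def read_bed_regions(path: str | Path) -> list[ROHRegion]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            regions.append(
                ROHRegion(
                    chrom=fields[0],
                    start_bp=int(fields[1]),
                    end_bp=int(fields[2]),
                    n_candidate_snps=1,
                    priority=None if len(fields) < 5 or fields[4].strip() == "." else float(fields[4]),
                )
            )
    return regions


def write_regions_tsv(path: str | Path, regions: Sequence[ROHRegion]) -> None:
    rows = [
        {
            "chrom": r.chrom,
            "start_bp": r.start_bp,
            "end_bp": r.end_bp,
            "n_snps": r.n_candidate_snps,
            "length_kb": round(r.length_kb, 3),
            "carrier_maf": None if r.carrier_maf is None else round(r.carrier_maf, 4),
            "priority": None if r.priority is None else round(r.priority, 4),
        }
        for r in regions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- small tables -----------------------------------------------------------


def write_known_tsv(path: str | Path, keys: Iterable[tuple[str, int, str, str]]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for chrom, pos, ref, alt in sorted(keys):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")


def read_known_tsv(path: str | Path) -> set[tuple[str, int, str, str]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    return {
        (r.chrom, int(r.pos), r.ref, r.alt) for r in df.itertuples(index=False)
    }
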