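"""Orthologous coding-site tables: degeneracy, CpG context, masks, file I/O.

Builds one row per orthologous coding base from paired gene models (equal
length, indel-free CDS blocks in two species), classifies each position's
codon degeneracy under the standard genetic code, flags CpG dinucleotide
context in either species' reference, and applies interval exclusion masks.

Coordinates are 0-based half-open throughout; VCF positions are converted
from 1-based at I/O. Degeneracy and allele patterns are always expressed on
the coding strand: variants of minus-strand genes are complemented at
ingest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger("cosnp")

__all__ = [
    "Degeneracy",
    "GeneModel",
    "classify_degeneracy",
    "flag_cpg",
    "build_site_table",
    "apply_masks",
    "cpg_flags",
    "read_fasta",
    "read_bed",
    "read_orthology_map",
    "load_gene_models",
    "read_vcf",
    "attach_variants",
]

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

_STANDARD = CodonTable.unambiguous_dna_by_id[1]


class Degeneracy(str, Enum):
    """Codon-position degeneracy class.

    ZERO: every substitution changes the amino acid. FOUR: every
    substitution is synonymous (third positions only, standard code).
    TWO_THREE: intermediate. AMBIGUOUS: conflicting assignments from
    overlapping genes; excluded from every denominator downstream.
    """

    ZERO = "zero"
    TWO_THREE = "two_three"
    FOUR = "four"
    AMBIGUOUS = "ambiguous"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_degeneracy(
    codon: str, codon_pos: int, table: CodonTable.CodonTable | None = None
) -> Degeneracy:
    """Degeneracy of one codon position.

    Substitutions creating a stop codon count as amino-acid-changing.
    Raises ``ValueError`` for stop codons, non-ACGT bases, or an invalid
    position.
    """
    if table is None:
        return _classify_standard(codon.upper(), codon_pos)
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"not a valid codon: {codon!r}")
    if codon in table.stop_codons:
        raise ValueError(f"stop codon has no degeneracy: {codon}")
    if codon_pos not in (0, 1, 2):
        raise ValueError(f"codon_pos must be 0, 1 or 2, got {codon_pos}")
    aa = table.forward_table[codon]
    n_syn = 0
    for b in _BASES:
        if b == codon[codon_pos]:
            continue
        alt = codon[:codon_pos] + b + codon[codon_pos + 1:]
        if alt not in table.stop_codons and table.forward_table[alt] == aa:
            n_syn += 1
    if n_syn == 0:
        return Degeneracy.ZERO
    if n_syn == 3:
        return Degeneracy.FOUR
    return Degeneracy.TWO_THREE


@lru_cache(maxsize=None)
def _classify_standard(codon: str, codon_pos: int) -> Degeneracy:
    return classify_degeneracy(codon, codon_pos, _STANDARD)


def flag_cpg(sequence: str, position: int) -> bool:
    """True iff the base participates in a CG dinucleotide.

    A C followed by G, or a G preceded by C, in the given reference
    sequence. CpG context is strand-symmetric (CG reverse-complements to
    CG), so the result is the same on either strand.
    """
    if not 0 <= position < len(sequence):
        raise IndexError(f"position {position} outside sequence of length {len(sequence)}")
    b = sequence[position].upper()
    if b == "C":
        return position + 1 < len(sequence) and sequence[position + 1].upper() == "G"
    if b == "G":
        return position > 0 and sequence[position - 1].upper() == "C"
    return False


@dataclass
class GeneModel:
    """Paired orthologous CDS of one gene in species A and B.

    Blocks are genomic 0-based half-open intervals listed in coding order
    (for minus-strand genes that is descending genomic coordinate);
    ``seq_a``/``seq_b`` are the spliced coding-strand sequences.
    """

    gene_id: str
    chrom_a: str
    blocks_a: list[tuple[int, int]]
    strand_a: str
    seq_a: str
    chrom_b: str
    blocks_b: list[tuple[int, int]]
    strand_b: str
    seq_b: str

    def validate(self) -> None:
        la = sum(e - s for s, e in self.blocks_a)
        lb = sum(e - s for s, e in self.blocks_b)
        if la != lb:
            raise ValueError(f"{self.gene_id}: CDS lengths differ between species")
        if la % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length {la} not a multiple of 3")
        if len(self.seq_a) != la or len(self.seq_b) != lb:
            raise ValueError(f"{self.gene_id}: sequence/block length mismatch")
        for blocks, pair_len in ((self.blocks_a, None), (self.blocks_b, None)):
            for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
                if max(s1, s2) < min(e1, e2):
                    raise ValueError(f"{self.gene_id}: overlapping CDS blocks")
        for seq, sp in ((self.seq_a, "A"), (self.seq_b, "B")):
            for i in range(0, len(seq) - 3, 3):
                if seq[i:i + 3].upper() in _STANDARD.stop_codons:
                    raise ValueError(f"{self.gene_id}: internal stop codon in species {sp}")

    def coords(self, species: str) -> np.ndarray:
        """Genomic coordinate of every coding position, in coding order."""
        blocks = self.blocks_a if species == "A" else self.blocks_b
        strand = self.strand_a if species == "A" else self.strand_b
        parts = []
        for s, e in blocks:
            rng = np.arange(s, e, dtype=np.int64)
            parts.append(rng if strand == "+" else rng[::-1])
        return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)


def build_site_table(
    models: Iterable[GeneModel],
    genome_a: Mapping[str, str] | None = None,
    genome_b: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One CodingSite row per coding base of every accepted gene.

    Genes failing validation (length not divisible by 3, internal stop,
    unequal block lengths) are skipped with a logged warning. A genomic
    position in species A covered by more than one gene with conflicting
    degeneracy is emitted once as AMBIGUOUS. CpG flags use the genomic
    context when reference genomes are supplied, otherwise the spliced
    coding sequence of each species.
    """
    frames = []
    for model in models:
        try:
            model.validate()
        except ValueError as exc:
            logger.warning("skipping gene: %s", exc)
            continue
        n = len(model.seq_a)
        idx = np.arange(n)
        seq_a = model.seq_a.upper()
        seq_b = model.seq_b.upper()
        degen = np.empty(n, dtype=object)
        for ci in range(n // 3):
            codon = seq_a[3 * ci: 3 * ci + 3]
            for cp in range(3):
                degen[3 * ci + cp] = classify_degeneracy(codon, cp).value
        coords_a = model.coords("A")
        coords_b = model.coords("B")
        if genome_a is not None:
            ref = genome_a[model.chrom_a]
            cpg_a = np.fromiter((flag_cpg(ref, int(c)) for c in coords_a), bool, n)
        else:
            cpg_a = np.fromiter((flag_cpg(seq_a, i) for i in range(n)), bool, n)
        if genome_b is not None:
            ref = genome_b[model.chrom_b]
            cpg_b = np.fromiter((flag_cpg(ref, int(c)) for c in coords_b), bool, n)
        else:
            cpg_b = np.fromiter((flag_cpg(seq_b, i) for i in range(n)), bool, n)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": model.gene_id,
                    "codon_index": idx // 3,
                    "codon_pos": idx % 3,
                    "chrom_a": model.chrom_a,
                    "coord_a": coords_a,
                    "strand_a": model.strand_a,
                    "ref_a": list(seq_a),
                    "chrom_b": model.chrom_b,
                    "coord_b": coords_b,
                    "strand_b": model.strand_b,
                    "ref_b": list(seq_b),
                    "degeneracy": degen,
                    "cpg_a": cpg_a,
                    "cpg_b": cpg_b,
                }
            )
        )
    if not frames:
        return _empty_site_table()
    sites = pd.concat(frames, ignore_index=True)
    # resolve overlapping-gene conflicts on species-A genomic position
    key = sites["chrom_a"].astype(str) + ":" + sites["coord_a"].astype(str)
    n_classes = sites.groupby(key)["degeneracy"].transform("nunique")
    sites.loc[n_classes > 1, "degeneracy"] = Degeneracy.AMBIGUOUS.value
    dup = key.duplicated()
    if dup.any():
        logger.warning("%d positions covered by multiple genes; kept one row each",
                       int(dup.sum()))
        sites = sites[~dup.values]
    sites = sites.reset_index(drop=True)
    sites["masked"] = False
    return sites


def _empty_site_table() -> pd.DataFrame:
    cols = ["gene_id", "codon_index", "codon_pos", "chrom_a", "coord_a", "strand_a",
            "ref_a", "chrom_b", "coord_b", "strand_b", "ref_b", "degeneracy",
            "cpg_a", "cpg_b", "masked"]
    return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})


def apply_masks(
    sites: pd.DataFrame,
    intervals_a: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    intervals_b: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> pd.DataFrame:
    """Set ``masked`` where coord_a or coord_b falls in an exclusion interval.

    Intervals are half-open, keyed by chromosome. Returns a copy; masked
    sites are excluded from all denominators downstream.
    """
    sites = sites.copy()
    masked = sites["masked"].to_numpy(copy=True) if "masked" in sites else np.zeros(len(sites), bool)
    for intervals, chrom_col, coord_col in (
        (intervals_a, "chrom_a", "coord_a"),
        (intervals_b, "chrom_b", "coord_b"),
    ):
        if not intervals:
            continue
        coords = sites[coord_col].to_numpy()
        chroms = sites[chrom_col].to_numpy()
        for chrom, ivals in intervals.items():
            on_chrom = chroms == chrom
            for start, end in ivals:
                masked |= on_chrom & (coords >= start) & (coords < end)
    sites["masked"] = masked
    return sites


def cpg_flags(sites: pd.DataFrame, mode: str = "either") -> pd.Series:
    """Combined CpG flag: ``either`` (default, conservative), ``both``, ``a``, ``b``."""
    if mode == "either":
        return sites["cpg_a"] | sites["cpg_b"]
    if mode == "both":
        return sites["cpg_a"] & sites["cpg_b"]
    if mode in ("a", "b"):
        return sites[f"cpg_{mode}"]
    raise ValueError(f"unknown CpG mode: {mode!r}")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_bed(path) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.setdefault(chrom, []).append((int(start), int(end)))
    return out


_ORTHOLOGY_COLS = ["gene_id", "chrom_A", "start_A", "end_A", "strand_A",
                   "chrom_B", "start_B", "end_B", "strand_B"]


def read_orthology_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_ORTHOLOGY_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"orthology map missing columns: {sorted(missing)}")
    bad = (df["end_A"] - df["start_A"]) != (df["end_B"] - df["start_B"])
    if bad.any():
        raise ValueError("orthology blocks must be equal length in both species")
    return df


def load_gene_models(
    orthology: pd.DataFrame | str,
    genome_a: Mapping[str, str],
    genome_b: Mapping[str, str],
) -> list[GeneModel]:
    """Assemble GeneModels from an orthology block map and both references.

    Rows of the map are colinear equal-length CDS blocks listed in coding
    order within each gene.
    """
    if not isinstance(orthology, pd.DataFrame):
        orthology = read_orthology_map(orthology)
    models = []
    for gene_id, grp in orthology.groupby("gene_id", sort=False):
        blocks_a = list(zip(grp["start_A"].astype(int), grp["end_A"].astype(int)))
        blocks_b = list(zip(grp["start_B"].astype(int), grp["end_B"].astype(int)))
        strand_a = grp["strand_A"].iloc[0]
        strand_b = grp["strand_B"].iloc[0]
        chrom_a = grp["chrom_A"].iloc[0]
        chrom_b = grp["chrom_B"].iloc[0]
        seq_a = _splice(genome_a[chrom_a], blocks_a, strand_a)
        seq_b = _splice(genome_b[chrom_b], blocks_b, strand_b)
        models.append(
            GeneModel(str(gene_id), chrom_a, blocks_a, strand_a, seq_a,
                      chrom_b, blocks_b, strand_b, seq_b)
        )
    return models


def _splice(chrom_seq: str, blocks: list[tuple[int, int]], strand: str) -> str:
    parts = [
        chrom_seq[s:e] if strand == "+" else reverse_complement(chrom_seq[s:e])
        for s, e in blocks
    ]
    return "".join(parts)


def read_vcf(path) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read biallelic SNVs from a VCF.

    Returns (variants, skipped): variants with 0-based ``coord``, genomic
    ``ref``/``alt`` alleles and ``maf`` (from INFO/AF when present, else
    from sample genotypes); a count of skipped records by reason.
    """
    import pysam

    skipped = {"multiallelic": 0, "not_snv": 0, "no_frequency": 0}
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                skipped["multiallelic"] += 1
                continue
            ref, alt = rec.ref, alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                skipped["not_snv"] += 1
                continue
            af = rec.info.get("AF")
            if af is not None:
                af = float(af[0] if isinstance(af, tuple) else af)
            else:
                counts = [0, 0]
                for sample in rec.samples.values():
                    for allele in sample["GT"]:
                        if allele is not None:
                            counts[allele] += 1
                total = counts[0] + counts[1]
                if total == 0 or counts[1] == 0 or counts[0] == 0:
                    skipped["no_frequency"] += 1
                    continue
                af = counts[1] / total
            rows.append((rec.chrom, rec.pos - 1, ref, alt, min(af, 1.0 - af)))
    for reason, count in skipped.items():
        if count:
            logger.info("read_vcf(%s): skipped %d records (%s)", path, count, reason)
    df = pd.DataFrame(rows, columns=["chrom", "coord", "ref", "alt", "maf"])
    return df, skipped


def attach_variants(
    sites: pd.DataFrame, variants: pd.DataFrame, species: str
) -> pd.DataFrame:
    """Map genomic variants onto the site table for one species ('A' or 'B').

    Returns per-variant rows carrying the site index and coding-strand
    allele pair (reference allele first). Variants at positions absent
    from the table, at masked sites, or whose reference allele disagrees
    with the site table are dropped with a logged count.
    """
    sp = species.lower()
    chrom_col, coord_col, ref_col, strand_col = (
        f"chrom_{sp}", f"coord_{sp}", f"ref_{sp}", f"strand_{sp}",
    )
    usable = sites[~sites["masked"]]
    lookup = pd.Series(
        usable.index,
        index=pd.MultiIndex.from_arrays([usable[chrom_col], usable[coord_col]]),
    )
    key = pd.MultiIndex.from_arrays([variants["chrom"], variants["coord"]])
    site_idx = lookup.reindex(key).to_numpy()
    hit = ~pd.isna(site_idx)
    n_dropped = int((~hit).sum())
    if n_dropped:
        logger.info("attach_variants(%s): %d variants outside usable sites",
                    species, n_dropped)
    var = variants.loc[hit].reset_index(drop=True)
    site_idx = site_idx[hit].astype(int)
    strands = sites[strand_col].to_numpy()[site_idx]
    refs = sites[ref_col].to_numpy()[site_idx]
    a1 = var["ref"].to_numpy(dtype=object)
    a2 = var["alt"].to_numpy(dtype=object)
    minus = strands == "-"
    comp = np.vectorize(lambda b: b.translate(_COMPLEMENT))
    if minus.any():
        a1[minus] = comp(a1[minus])
        a2[minus] = comp(a2[minus])
    consistent = a1 == refs
    if not consistent.all():
        logger.warning("attach_variants(%s): %d variants with reference mismatch dropped",
                       species, int((~consistent).sum()))
    out = pd.DataFrame(
        {
            "site": site_idx,
            "species": species,
            "allele_ref": a1,
            "allele_alt": a2,
            "maf": var["maf"].to_numpy(),
        }
    )[consistent]
    return out.reset_index(drop=True)
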