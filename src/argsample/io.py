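"""Readers and writers: FASTA alignments, VCF-to-haplotype import,
Newick/TSV outputs.

All user-facing coordinates are 1-based inclusive; everything internal
is 0-based half-open.  Writers are deterministic given fixed inputs.
"""

from __future__ import annotations

from typing import Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .arg import Arg, marginal_trees, enumerate_breakpoints, tmrca_profile_of_arg
from .likelihood import Alignment

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_vcf_haplotypes",
    "write_marginal_trees",
    "breakpoints_tsv",
    "tmrca_tsv",
]


def read_fasta(path) -> Alignment:
    """Read an equal-length nucleotide alignment (wrapped or unwrapped
    FASTA); sequences are case-folded to uppercase."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    names = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        detail = "; ".join(f"{n}: {len(s)}" for n, s in zip(names, seqs))
        raise ValueError(f"{path}: ragged sequence lengths ({detail})")
    return Alignment.from_strings(names, seqs)


def write_fasta(alignment: Alignment, path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(alignment.sequence_str(i)), id=name, description="")
        for i, name in enumerate(alignment.names)
    ]
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            s = str(rec.seq)
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def read_vcf_haplotypes(path, samples: Optional[Sequence[str]] = None,
                        mode: str = "variant_only",
                        region: Optional[tuple[str, int, int]] = None,
                        reference: Optional[str] = None) -> Alignment:
    """Import phased haplotypes from a VCF.

    ``mode='variant_only'``: columns are the variant sites only; the
    number of skipped monomorphic positions inside ``region`` (when
    given) is recorded in ``alignment.invariant_pad`` so the likelihood
    can treat them as constant columns.  ``mode='region_fill'``:
    REF-filled monomorphic columns between variants inside ``region``
    (region required).

    Diploid genotypes must be phased ('|'); haploid calls (as on a male
    X chromosome) are accepted as single haplotypes.  Indels and other
    non-SNP records are skipped with a warning on stderr.
    """
    import sys

    import pysam

    if mode not in ("variant_only", "region_fill"):
        raise ValueError(f"unknown VCF import mode {mode!r}")
    if mode == "region_fill" and region is None:
        raise ValueError("region_fill mode requires an explicit region")
    vcf = pysam.VariantFile(str(path))
    if samples is None:
        samples = list(vcf.header.samples)
    columns = []  # (pos0, ref, per-haplotype bases)
    hap_names: Optional[list[str]] = None
    for rec in vcf:
        if region is not None:
            chrom, start, end = region
            if rec.chrom != chrom or not (start < rec.pos <= end):
                continue
        alleles = rec.alleles
        if alleles is None or any(len(a) != 1 for a in alleles):
            print(f"warning: skipping non-SNP record at {rec.chrom}:{rec.pos}",
                  file=sys.stderr)
            continue
        bases = []
        names = []
        for sample in samples:
            call = rec.samples[sample]
            gt = call.get("GT")
            if gt is None or all(a is None for a in gt):
                gt = tuple(None for _ in (gt or (None,)))
            phased = call.phased or len([a for a in gt if a is not None]) <= 1
            if len(gt) > 1 and not phased:
                raise ValueError(
                    f"unphased genotype for sample {sample} at "
                    f"{rec.chrom}:{rec.pos} ('/' separator); phased data required"
                )
            for i, allele_idx in enumerate(gt):
                names.append(f"{sample}" if len(gt) == 1 else f"{sample}_{i + 1}")
                bases.append("N" if allele_idx is None else alleles[allele_idx])
        if hap_names is None:
            hap_names = names
        elif names != hap_names:
            raise ValueError("inconsistent ploidy across VCF records")
        columns.append((rec.pos - 1, alleles[0], bases))
    if hap_names is None:
        raise ValueError(f"{path}: no usable SNP records")
    if mode == "variant_only":
        seqs = ["".join(col[2][i] for col in columns) for i in range(len(hap_names))]
        invariant = None
        if region is not None:
            span = region[2] - region[1]
            invariant = {"invariant_columns": span - len(columns)}
        aln = Alignment.from_strings(hap_names, seqs)
        aln.invariant_pad = invariant
        return aln
    # region_fill: monomorphic positions between variants take the
    # reference base when a region reference sequence is supplied,
    # otherwise N (missing, uninformative for the likelihood)
    _, start, end = region
    L = end - start
    if reference is not None and len(reference) != L:
        raise ValueError("reference length does not match region span")
    base_row = list(reference.upper()) if reference is not None else ["N"] * L
    rows = [list(base_row) for _ in hap_names]
    for pos0, _ref, bases in columns:
        j = pos0 - start
        if not (0 <= j < L):
            continue
        for i in range(len(hap_names)):
            rows[i][j] = bases[i]
    return Alignment.from_strings(hap_names, ["".join(r) for r in rows])


# ---------------------------------------------------------------------------
# ARG-derived text outputs
# ---------------------------------------------------------------------------

def write_marginal_trees(arg: Arg, path) -> None:
    """Newick per marginal-tree interval, with 1-based inclusive site
    ranges in a comment column."""
    with open(path, "w") as fh:
        for iv, tree in marginal_trees(arg):
            fh.write(f"[sites {iv.start + 1}-{iv.end}] {tree.newick()}\n")


def breakpoints_tsv(arg: Arg) -> str:
    lines = ["site\theight\tclass"]
    for rec in enumerate_breakpoints(arg):
        lines.append(f"{rec.site + 1}\t{rec.height:.8g}\t{rec.detectability}")
    return "\n".join(lines) + "\n"


def tmrca_tsv(arg: Arg) -> str:
    lines = ["site_start\tsite_end\ttmrca"]
    for iv, h in tmrca_profile_of_arg(arg):
        lines.append(f"{iv.start + 1}\t{iv.end}\t{h:.8g}")
    return "\n".join(lines) + "\n"
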