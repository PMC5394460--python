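"""Standard-format I/O: VCF v4.2 (INFO MQ/QD/HRun, FORMAT GT:DP:GQ), BED
regions, truth/karyotype TSVs.

VCF positions are 1-based on disk; internal interval types are 0-based
half-open.  Reading goes through cyvcf2; only biallelic SNVs are kept and
the count of excluded multiallelic records is logged.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .dimred import GenotypeMatrix
from .simulate import TruthRecord
from .variant_filter import SampleCall, VariantSite

logger = logging.getLogger(__name__)

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_truth_tsv",
    "read_bed",
    "genotype_matrix_from_sites",
    "write_karyotype_tsv",
]

_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
##INFO=<ID=HRun,Number=1,Type=Integer,Description="Homopolymer run length">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""

_GT_STRINGS = {None: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(sites: list[VariantSite], samples: list[str], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_HEADER)
        contigs = []
        for s in sites:
            if s.chrom not in contigs:
                contigs.append(s.chrom)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for s in sites:
            info = f"MQ={s.mq:.2f};QD={s.qd:.2f};HRun={s.hrun}"
            fields = [s.chrom, str(s.pos), ".", s.ref, s.alt, ".", "PASS", info, "GT:DP:GQ"]
            for sample in samples:
                call = s.calls[sample]
                fields.append(f"{_GT_STRINGS[call.gt]}:{call.dp}:{call.gq}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path) -> tuple[list[VariantSite], list[str]]:
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or variant.ALT[0] is None:
            n_multi += 1
            continue
        dps = variant.format("DP")
        gqs = variant.format("GQ")
        calls = {}
        for i, sample in enumerate(samples):
            g = variant.genotypes[i]
            alleles = g[:-1]
            gt = None if -1 in alleles else int(sum(alleles))
            calls[sample] = SampleCall(
                gt=gt,
                dp=int(dps[i][0]) if dps is not None else 0,
                gq=int(gqs[i][0]) if gqs is not None else 0,
            )
        info = dict(variant.INFO)
        sites.append(
            VariantSite(
                chrom=variant.CHROM,
                pos=variant.POS,
                ref=variant.REF,
                alt=variant.ALT[0],
                mq=float(info.get("MQ", 0.0)),
                qd=float(info.get("QD", 0.0)),
                hrun=int(info.get("HRun", 0)),
                calls=calls,
            )
        )
    if n_multi:
        logger.info("read_vcf: excluded %d multiallelic records", n_multi)
    return sites, samples


def genotype_matrix_from_sites(
    sites: list[VariantSite], samples: list[str], allow_missing: bool = False
) -> GenotypeMatrix:
    """Dosage matrix from variant records (missing as -1 when allowed)."""
    dosage = np.zeros((len(samples), len(sites)), dtype=np.int64)
    for j, s in enumerate(sites):
        for i, sample in enumerate(samples):
            gt = s.calls[sample].gt
            if gt is None:
                if not allow_missing:
                    raise ValueError(
                        f"missing genotype at {s.chrom}:{s.pos} for {sample}; "
                        "run the missingless filter first"
                    )
                dosage[i, j] = -1
            else:
                dosage[i, j] = gt
    loci = pd.DataFrame(
        {"chrom": [s.chrom for s in sites], "pos": [s.pos - 1 for s in sites]}
    )
    return GenotypeMatrix(dosages=dosage, samples=list(samples), loci=loci)


def write_truth_tsv(truths: list[TruthRecord], path) -> None:
    rows = []
    for t in truths:
        for arm, haps in t.intervals.items():
            for h, blocks in enumerate(haps):
                for start, end, species in blocks:
                    rows.append((t.individual, arm, start, end, h, species))
    pd.DataFrame(
        rows, columns=["individual", "arm", "start", "end", "haplotype", "ancestry"]
    ).to_csv(path, sep="\t", index=False)


def read_bed(path) -> pd.DataFrame:
    """BED with a 4th label column -> DataFrame(chrom, start, end, label)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError("expected a 4-column BED (chrom, start, end, label)")
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "label"]
    return df


def regions_to_frame(spans) -> pd.DataFrame:
    """Labelled Span tuples -> BED-like frame."""
    return pd.DataFrame(spans, columns=["chrom", "start", "end", "label"])


def write_karyotype_tsv(labels: list[tuple[str, str]], path) -> None:
    rows = [(f"ind{i:03d}", l2r, l2l) for i, (l2r, l2l) in enumerate(labels)]
    pd.DataFrame(rows, columns=["individual", "karyotype_2R", "karyotype_2L"]).to_csv(
        path, sep="\t", index=False
    )
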