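"""Reading and writing genotype matrices (VCF and CSV) and kernels."""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .genotypes import GenotypeMatrix
from .qc import KinshipKernel

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path: str) -> None:
    """Write a plain-text VCF 4.2 with GT (and DP when depth is present).

    Dosages must be integral (0/1/2); heterozygotes are written unphased.
    """
    obs = genotypes.dosages[~genotypes.missing]
    if obs.size and not np.allclose(obs, np.round(obs)):
        raise ConfigurationError("cannot write fractional (imputed-mean) dosages to VCF")
    with_depth = genotypes.depth is not None
    fmt = "GT:DP" if with_depth else "GT"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if with_depth:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in genotypes.snp_map["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.line_ids) + "\n")
        for j, rec in genotypes.snp_map.iterrows():
            calls = []
            for i in range(genotypes.n_lines):
                if genotypes.missing[i, j]:
                    gt = "./."
                else:
                    gt = _GT_STRINGS[int(round(genotypes.dosages[i, j]))]
                if with_depth:
                    gt += f":{int(genotypes.depth[i, j])}"
                calls.append(gt)
            fh.write(f"{rec['chrom']}\t{rec['pos']}\t{rec['chrom']}_{rec['pos']}\t"
                     f"{rec['ref']}\t{rec['alt']}\t.\tPASS\t.\t{fmt}\t"
                     + "\t".join(calls) + "\n")


def read_vcf(path: str) -> GenotypeMatrix:
    """Read GT dosages (alt-allele count) and optional DP from a VCF."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    line_ids = list(vcf.samples)
    dosages, missing, depths, rows = [], [], [], []
    any_depth = False
    for v in vcf:
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = np.asarray(v.gt_types)
        dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=0.0)
        miss = gt == 2
        dosages.append(dos)
        missing.append(miss)
        try:
            d = v.format("DP")
        except KeyError:
            d = None
        if d is not None:
            any_depth = True
            depths.append(np.asarray(d, dtype=float).reshape(-1))
        else:
            depths.append(np.zeros(len(line_ids)))
        rows.append((v.CHROM, int(v.POS), v.REF, ",".join(v.ALT) if v.ALT else "."))
    vcf.close()
    snp_map = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(
        dosages=np.array(dosages).T,
        missing=np.array(missing).T,
        line_ids=line_ids,
        snp_map=snp_map,
        depth=np.array(depths).T.astype(int) if any_depth else None,
    )


def write_dosage_csv(genotypes: GenotypeMatrix, path: str,
                     map_path: Optional[str] = None) -> None:
    """Line x marker CSV (missing as empty cells) plus an optional map CSV."""
    genotypes.to_frame().to_csv(path, index_label="line_id")
    if map_path:
        genotypes.snp_map.to_csv(map_path, index=False)


def read_dosage_csv(path: str, map_path: Optional[str] = None) -> GenotypeMatrix:
    """Inverse of :func:`write_dosage_csv`.

    Without a map file, marker names of the form ``<chrom>_<pos>`` are
    parsed back into the map (alleles default to A/T).
    """
    df = pd.read_csv(path, index_col=0)
    if map_path and os.path.exists(map_path):
        snp_map = pd.read_csv(map_path)
    else:
        parts = [c.rsplit("_", 1) for c in df.columns]
        snp_map = pd.DataFrame({
            "chrom": [p[0] for p in parts],
            "pos": [int(p[1]) for p in parts],
            "ref": "A", "alt": "T",
        })
    vals = df.to_numpy(dtype=float)
    missing = np.isnan(vals)
    vals = np.where(missing, 0.0, vals)
    return GenotypeMatrix(dosages=vals, missing=missing,
                          line_ids=[str(i) for i in df.index], snp_map=snp_map)


def write_kernel_csv(kernel: KinshipKernel, path: str) -> None:
    kernel.to_frame().to_csv(path, index_label="line_id")


def read_kernel_csv(path: str) -> KinshipKernel:
    df = pd.read_csv(path, index_col=0)
    return KinshipKernel(matrix=df.to_numpy(dtype=float), line_ids=[str(i) for i in df.index])
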