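"""Text-format input/output: TSV tables, dosage VCF, run directories."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GeneNetwork, GenotypeMatrix, SimConfig, SimulatedPhenotype


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write genotypes as a VCF with a DS (dosage) FORMAT field.

    The effect allele is written as ALT so DS counts ALT copies; per-variant
    INFO scores go to the INFO column.
    """
    samples = [f"S{i:06d}" for i in range(G.n_samples)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j, row in enumerate(G.variants.itertuples(index=False)):
            ds = "\t".join(f"{d:g}" for d in G.dosages[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.other_allele}\t"
                f"{row.effect_allele}\t.\tPASS\tINFO={row.info:.4f}\tDS\t{ds}\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a dosage VCF (DS FORMAT field, falling back to hard GT calls)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    rows = []
    dosage_cols = []
    for rec in vcf:
        alt = rec.ALT[0] if rec.ALT else "."
        try:
            ds = np.asarray(rec.format("DS"), dtype=float).ravel()
        except (KeyError, TypeError, ValueError):
            gt = np.asarray(rec.genotype.array())[:, :2]
            ds = np.clip(gt, 0, None).sum(axis=1).astype(float)
        info = rec.INFO.get("INFO", 1.0)
        rows.append(
            {
                "variant_id": rec.ID or f"{rec.CHROM}:{rec.POS}_{rec.REF}_{alt}",
                "chrom": str(rec.CHROM),
                "pos": int(rec.POS),
                "effect_allele": alt,
                "other_allele": rec.REF,
                "eaf": float(ds.mean() / 2.0),
                "info": float(info),
            }
        )
        dosage_cols.append(ds)
    dosages = np.column_stack(dosage_cols) if dosage_cols else np.empty((0, 0))
    return GenotypeMatrix(dosages=dosages, variants=pd.DataFrame(rows))


def write_network_tsv(network: GeneNetwork, path: str | Path) -> None:
    """Square correlation matrix with gene names as header and index."""
    pd.DataFrame(network.corr, index=network.genes, columns=network.genes).to_csv(
        path, sep="\t"
    )


def read_network_tsv(path: str | Path, flags: pd.DataFrame | None = None) -> GeneNetwork:
    mat = pd.read_csv(path, sep="\t", index_col=0)
    genes = list(mat.index)
    if flags is None:
        flags = pd.DataFrame(
            {"core": False, "gwas": False}, index=pd.Index(genes, name="gene")
        )
    return GeneNetwork(genes=genes, corr=mat.to_numpy(), flags=flags)


def write_run(
    outdir: str | Path,
    config: SimConfig,
    G: GenotypeMatrix,
    phenotype: SimulatedPhenotype | None = None,
    vcf: bool = True,
) -> Path:
    """Emit a simulated cohort under a run directory with the config echoed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = asdict(config)
    cfg["causal_spec"] = [list(t) for t in cfg["causal_spec"]]
    cfg["covariate_effects"] = dict(cfg["covariate_effects"])
    (outdir / "config.json").write_text(json.dumps(cfg, indent=2))
    if vcf:
        write_vcf(G, outdir / "genotypes.vcf")
    else:
        dos = pd.DataFrame(G.dosages, columns=G.variants["variant_id"])
        write_tsv(dos, outdir / "genotypes.tsv")
    write_tsv(G.variants, outdir / "variants.tsv")
    if phenotype is not None:
        write_tsv(phenotype.table, outdir / "phenotypes.tsv")
        truth = pd.DataFrame(
            {
                "variant_index": list(phenotype.truth.sparse_effects),
                "beta": list(phenotype.truth.sparse_effects.values()),
            }
        )
        write_tsv(truth, outdir / "truth_sparse_effects.tsv")
    return outdir


def write_loci_bed(clumped: pd.DataFrame, variants: pd.DataFrame, path: str | Path) -> None:
    """Write clumped loci as BED (0-based half-open intervals spanning the
    clump members), with the tag variant ID as the interval name."""
    merged = clumped.merge(variants[["variant_id", "chrom", "pos"]], on="variant_id")
    rows = []
    for locus, sub in merged.groupby("locus"):
        tag = sub.loc[sub["is_tag"], "variant_id"].iloc[0]
        rows.append(
            (str(sub["chrom"].iloc[0]), int(sub["pos"].min()) - 1,
             int(sub["pos"].max()), tag)
        )
    with open(path, "w") as fh:
        for chrom, start, end, name in sorted(rows):
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def write_regions_bed(regions, path: str | Path) -> None:
    """Write fine-mapping regions as BED with the causal-count K as score."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\tregion\t{r.k}\n")
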