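"""Plain-text table I/O for every pipeline stage.

Feature tables are TSV with the feature identifier in the first column
and one column per sample; optional ``#``-prefixed comment lines record
provenance (normalization tag, thresholds).  Genotypes are accepted as
a TSV dosage matrix (rows = samples, columns = locus ids, entries
0/1/2/NA) with an optional locus metadata file, or as VCF through
cyvcf2 when that extra is installed.  Synthetic cohorts are written in
the same dialects the real-data path reads, so fixtures and real inputs
are interchangeable.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .abundance import FeatureTable
from .genotype import CodedGenotypeMatrix, GenotypeMatrix

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_lengths",
    "write_lengths",
    "read_covariates",
    "write_covariates",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_vcf",
    "write_coded_matrix",
    "read_annotation_map",
]


def read_feature_table(path, lengths_path=None) -> FeatureTable:
    """Read a features x samples TSV (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    lengths = read_lengths(lengths_path) if lengths_path else None
    return FeatureTable(df.astype(float), lengths=lengths)


def write_feature_table(table: FeatureTable, path, extra_comments=()):
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# normalization={table.normalization or 'raw'}\n")
        for line in extra_comments:
            fh.write(f"# {line}\n")
        table.values.to_csv(fh, sep="\t", index_label="feature_id")


def read_lengths(path) -> pd.Series:
    """Two-column TSV: feature id, length in bases."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    s = df.iloc[:, 0].astype(int)
    s.index = s.index.astype(str)
    s.name = "length"
    return s


def write_lengths(lengths: pd.Series, path):
    lengths.rename("length").to_csv(path, sep="\t", index_label="feature_id")


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    return df


def write_covariates(cov: pd.DataFrame, path):
    cov.to_csv(path, sep="\t", index_label="sample_id")


def read_genotypes_tsv(path, loci_path=None) -> GenotypeMatrix:
    """Dosage TSV (rows = samples, columns = loci, entries 0/1/2/NA).

    ``loci_path`` may give a TSV of locus id, chrom, pos; without it all
    loci sit on one chromosome in column order.
    """
    calls = pd.read_csv(path, sep="\t", index_col=0, comment="#").astype(float)
    calls.index = calls.index.astype(str)
    if loci_path:
        loci = pd.read_csv(loci_path, sep="\t", index_col=0, comment="#")
        loci.index = loci.index.astype(str)
        loci = loci.loc[calls.columns]
    else:
        loci = pd.DataFrame(
            {"chrom": "1", "pos": np.arange(calls.shape[1])}, index=calls.columns
        )
    return GenotypeMatrix(calls, loci)


def write_genotypes_tsv(g: GenotypeMatrix, path, loci_path=None):
    g.calls.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")
    if loci_path:
        g.loci.to_csv(loci_path, sep="\t", index_label="locus_id")


def read_vcf(path) -> GenotypeMatrix:
    """Read GT calls from a (possibly bgzipped) VCF via cyvcf2.

    Multi-allelic sites are dropped with a warning; missing genotypes
    become NaN.  Minor-allele orientation follows the ALT allele count.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading VCF requires the cyvcf2 extra") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, ids, chroms, poss = [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = np.array([g[:2] for g in var.genotypes], dtype=float)
        gts[gts < 0] = np.nan
        cols.append(gts.sum(axis=1))
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
    if n_multi:
        warnings.warn(f"dropped {n_multi} multi-allelic site(s)", stacklevel=2)
    calls = pd.DataFrame(np.column_stack(cols), index=samples, columns=ids)
    loci = pd.DataFrame({"chrom": chroms, "pos": poss}, index=ids)
    return GenotypeMatrix(calls, loci)


def write_coded_matrix(coded: CodedGenotypeMatrix, path, groups_path=None):
    """Coded TSV plus a two-column (column id, locus id) group map."""
    coded.columns.to_csv(path, sep="\t", index_label="sample_id")
    if groups_path:
        coded.groups.rename("locus_id").to_csv(
            groups_path, sep="\t", index_label="column_id"
        )


def read_annotation_map(pairs_path, names_path=None):
    """Two-column TSV (feature id, term id), optional term-name TSV."""
    from .enrichment import AnnotationMap

    pairs = pd.read_csv(pairs_path, sep="\t", comment="#")
    names = {}
    if names_path:
        nd = pd.read_csv(names_path, sep="\t", index_col=0, comment="#")
        names = nd.iloc[:, 0].to_dict()
    return AnnotationMap.from_pairs(
        pairs.iloc[:, :2].astype(str).itertuples(index=False, name=None), names
    )
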