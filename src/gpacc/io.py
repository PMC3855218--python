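"""File I/O: PLINK ``.raw``-style genotype tables, plain TSV matrices,
phenotype/GRM/scenario CSVs and YAML configuration."""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .crossval import CVScenarioTable
from .relmat import GRM, GenotypeMatrix, InputError
from .simdata import PopulationConfig, QuasiPhenotypes

__all__ = [
    "read_genotypes",
    "write_genotypes_raw",
    "write_genotypes_tsv",
    "read_phenotypes",
    "write_phenotypes",
    "read_grm",
    "write_grm",
    "read_cv_table",
    "write_cv_table",
    "read_config",
    "write_config",
]

_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def read_genotypes(path) -> GenotypeMatrix:
    """Read a PLINK ``.raw`` additive table or a plain TSV genotype matrix.

    A ``.raw`` file is recognised by its six leading metadata columns
    (FID IID PAT MAT SEX PHENOTYPE); a TSV matrix has an ``id`` first
    column and one column per marker.  Missing codes are rejected.
    """
    df = pd.read_csv(path, sep=r"\s+")
    if list(df.columns[:6]) == _RAW_META:
        ids = df["IID"].astype(str).tolist()
        geno = df.drop(columns=_RAW_META)
    else:
        ids = df.iloc[:, 0].astype(str).tolist()
        geno = df.iloc[:, 1:]
    if geno.isna().any().any():
        raise InputError(f"missing genotype codes in {path}; impute first")
    return GenotypeMatrix(
        geno.to_numpy(dtype=np.int8), ids, [str(c) for c in geno.columns]
    )


def write_genotypes_raw(genotypes: GenotypeMatrix, path) -> None:
    """Write genotypes in the PLINK ``.raw`` whitespace dialect."""
    n = genotypes.n_individuals
    meta = pd.DataFrame(
        {
            "FID": genotypes.individual_ids,
            "IID": genotypes.individual_ids,
            "PAT": 0,
            "MAT": 0,
            "SEX": [0] * n,
            "PHENOTYPE": -9,
        }
    )
    geno = pd.DataFrame(genotypes.values, columns=genotypes.marker_ids)
    pd.concat([meta, geno], axis=1).to_csv(path, sep=" ", index=False)


def write_genotypes_tsv(genotypes: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        genotypes.values,
        columns=genotypes.marker_ids,
        index=pd.Index(genotypes.individual_ids, name="id"),
    )
    df.to_csv(path, sep="\t")


def read_phenotypes(path) -> QuasiPhenotypes:
    """Read a phenotype CSV with columns id, ebv, ebv_accuracy."""
    df = pd.read_csv(path)
    required = {"id", "ebv", "ebv_accuracy"}
    if not required.issubset(df.columns):
        raise InputError(f"phenotype file needs columns {sorted(required)}")
    return QuasiPhenotypes(
        df["id"].astype(str).tolist(),
        df["ebv"].to_numpy(float),
        df["ebv_accuracy"].to_numpy(float),
    )


def write_phenotypes(phenotypes: QuasiPhenotypes, path) -> None:
    pd.DataFrame(
        {
            "id": phenotypes.ids,
            "ebv": phenotypes.ebv,
            "ebv_accuracy": phenotypes.ebv_accuracy,
        }
    ).to_csv(path, index=False)


def read_grm(path) -> GRM:
    df = pd.read_csv(path, index_col=0)
    meta_path = str(path) + ".meta.yaml"
    try:
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh)
    except FileNotFoundError:
        meta = {}
    mat = df.to_numpy(float)
    return GRM(
        0.5 * (mat + mat.T),
        int(meta.get("n_markers_used", 0) or mat.shape[1]),
        float(meta.get("scaling_constant", 1.0)),
        [str(c) for c in df.columns],
    )


def write_grm(grm: GRM, path) -> None:
    pd.DataFrame(grm.matrix, index=grm.individual_ids, columns=grm.individual_ids).to_csv(path)
    with open(str(path) + ".meta.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "n_markers_used": int(grm.n_markers_used),
                "scaling_constant": float(grm.scaling_constant),
            },
            fh,
        )


def read_cv_table(path) -> CVScenarioTable:
    """Read a scenario CSV with columns k, n_train, replicate, accuracy."""
    return CVScenarioTable.from_frame(pd.read_csv(path))


def write_cv_table(table: CVScenarioTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_config(path) -> PopulationConfig:
    with open(path) as fh:
        return PopulationConfig(**yaml.safe_load(fh))


def write_config(config: PopulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: getattr(config, k) for k in config.__dataclass_fields__}, fh)
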