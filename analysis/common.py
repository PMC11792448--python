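"""Shared file-loading helpers for the analysis drivers."""

from pathlib import Path

import pandas as pd

from mockdebias.bias import close


def load_species(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    df.index = df.index.astype(str)
    return df


def load_sample_info(metadata_path: Path) -> pd.DataFrame:
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
    meta["protocol"] = meta[["kit", "lysis", "buffer"]].fillna("").agg("_".join, axis=1)
    meta.loc[meta[["kit", "lysis", "buffer"]].isna().any(axis=1), "protocol"] = ""
    return meta


def load_expected(design_path: Path) -> dict[str, pd.Series]:
    df = pd.read_csv(design_path, sep="\t")
    return {
        sclass: close(grp.set_index("taxon")["expected"])
        for sclass, grp in df.groupby("sample_class")
    }


def dna_design_from_ids(sample_info: pd.DataFrame) -> dict[str, str]:
    """DNA-mock sample ids follow 'dna_<design>_<replicate>' in the fixtures."""
    out = {}
    for sid, row in sample_info.iterrows():
        if row["sample_class"] == "dna_mock":
            out[sid] = sid.split("_")[1] + "_mock"
    return out
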