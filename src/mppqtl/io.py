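"""Readers and writers for the pipeline's delimited text formats.

Comma-separated text is the canonical interchange; every table written by
the pipeline carries a header comment with the tool version, a config hash
and the seed, and round-trips losslessly (dosages exactly, probabilities to
1e-12).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genmap import GeneticMap
from .ibd import IBDTensor
from .simulate import CrossingPlan, Family, GenotypeTable

__all__ = [
    "read_map",
    "write_map",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_plan",
    "write_plan",
    "read_founders",
    "write_founders",
    "read_ibd",
    "write_ibd",
    "read_results",
    "write_results",
    "config_hash",
]


class ParseError(ValueError):
    """Raised for malformed input files, naming the offending entry."""


def config_hash(config: dict | None) -> str:
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header(seed=None, config=None) -> str:
    return (
        f"# mppqtl v{__version__} config={config_hash(config)} seed={seed}\n"
    )


def _write_frame(df: pd.DataFrame, path, seed, config, index=False, float_format=None):
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(seed, config))
        df.to_csv(fh, index=index, float_format=float_format)


# -- genetic map ------------------------------------------------------------


def write_map(gmap: GeneticMap, path, seed=None, config=None) -> None:
    _write_frame(gmap.table, path, seed, config)


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path, comment="#")
    return GeneticMap(df)


# -- genotype dosages -------------------------------------------------------


def write_genotypes(table: GenotypeTable, path, seed=None, config=None) -> None:
    df = table.to_frame()
    df.insert(0, "family", table.family_labels)
    df.index.name = "individual"
    _write_frame(df, path, seed, config, index=True)


def read_genotypes(path, gmap: GeneticMap) -> GenotypeTable:
    df = pd.read_csv(path, comment="#", index_col="individual")
    fams = df.pop("family").to_numpy() if "family" in df.columns else np.array(["F1"] * len(df))
    unknown = [c for c in df.columns if c not in gmap._index]
    if unknown:
        raise ParseError(f"genotype column {unknown[0]!r} is not a map marker")
    missing = [m for m in gmap.markers if m not in df.columns]
    if missing:
        raise ParseError(f"map marker {missing[0]!r} missing from genotype file")
    df = df[list(gmap.markers)]
    dos = df.to_numpy(dtype=float)
    valid = np.isnan(dos) | np.isin(dos, (0.0, 1.0, 2.0))
    if not valid.all():
        i, j = np.argwhere(~valid)[0]
        raise ParseError(
            f"invalid dosage {dos[i, j]!r} for individual {df.index[i]!r} "
            f"at marker {df.columns[j]!r}"
        )
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"duplicate individual id {dup!r}")
    return GenotypeTable(list(df.index), fams, dos, gmap)


# -- founder alleles --------------------------------------------------------


def write_founders(founders: np.ndarray, gmap: GeneticMap, path, seed=None, config=None) -> None:
    df = pd.DataFrame(
        founders,
        index=[f"P{j + 1}" for j in range(founders.shape[0])],
        columns=gmap.markers,
    )
    df.index.name = "founder"
    _write_frame(df, path, seed, config, index=True)


def read_founders(path, gmap: GeneticMap) -> np.ndarray:
    df = pd.read_csv(path, comment="#", index_col="founder")
    unknown = [c for c in df.columns if c not in gmap._index]
    if unknown:
        raise ParseError(f"founder column {unknown[0]!r} is not a map marker")
    df = df[list(gmap.markers)]
    return df.to_numpy(dtype=int)


# -- phenotypes -------------------------------------------------------------


def write_phenotypes(individuals, y, path, seed=None, config=None) -> None:
    df = pd.DataFrame({"individual": individuals, "value": np.asarray(y, float)})
    _write_frame(df, path, seed, config)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if not {"individual", "value"}.issubset(df.columns):
        raise ParseError("phenotype file needs columns individual,value")
    if df["individual"].duplicated().any():
        dup = df.loc[df["individual"].duplicated(), "individual"].iloc[0]
        raise ParseError(f"duplicate phenotyped individual {dup!r}")
    return df


# -- crossing plans ---------------------------------------------------------


def write_plan(plan: CrossingPlan, path, seed=None, config=None) -> None:
    doc = {
        "design": plan.design_type,
        "final_generation": plan.final_generation,
        "n_founders": plan.n_founders,
        "families": [
            {"id": f.family_id, "parents": list(f.parents), "size": f.size}
            for f in plan.families
        ],
    }
    with open(path, "w") as fh:
        fh.write(_header(seed, config))
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_plan(path) -> CrossingPlan:
    text = Path(path).read_text()
    doc = yaml.safe_load("\n".join(l for l in text.splitlines() if not l.startswith("#")))
    try:
        fams = tuple(
            Family(str(f["id"]), tuple(int(p) for p in f["parents"]), int(f["size"]))
            for f in doc["families"]
        )
        return CrossingPlan(
            doc["design"], fams, int(doc["final_generation"]), int(doc["n_founders"])
        )
    except (KeyError, TypeError) as exc:
        raise ParseError(f"malformed plan file: {exc}") from exc


# -- IBD posteriors ---------------------------------------------------------


def write_ibd(tensor: IBDTensor, path, seed=None, config=None) -> None:
    """Long format: individual, marker, founder, probability."""
    n, m, p = tensor.probs.shape
    ind = np.repeat(tensor.individuals, m * p)
    mark = np.tile(np.repeat(tensor.gmap.markers, p), n)
    founder = np.tile(np.arange(p) + 1, n * m)
    df = pd.DataFrame(
        {
            "individual": ind,
            "marker": mark,
            "founder": founder,
            "probability": tensor.probs.ravel(),
        }
    )
    _write_frame(df, path, seed, config, float_format="%.15g")


def read_ibd(path, gmap: GeneticMap) -> IBDTensor:
    df = pd.read_csv(path, comment="#")
    individuals = list(dict.fromkeys(df["individual"]))
    n_founders = int(df["founder"].max())
    probs = np.full((len(individuals), gmap.n_markers, n_founders), np.nan)
    ind_idx = {v: i for i, v in enumerate(individuals)}
    unknown = set(df["marker"]) - set(gmap.markers)
    if unknown:
        raise ParseError(f"IBD marker {sorted(unknown)[0]!r} is not on the map")
    probs[
        df["individual"].map(ind_idx).to_numpy(),
        df["marker"].map(gmap._index).to_numpy(),
        df["founder"].to_numpy() - 1,
    ] = df["probability"].to_numpy()
    return IBDTensor(individuals, gmap, n_founders, probs)


# -- generic result tables --------------------------------------------------


def write_results(df: pd.DataFrame, path, seed=None, config=None) -> None:
    _write_frame(df, path, seed, config, float_format="%.10g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
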