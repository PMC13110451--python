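"""Dataset bundle readers/writers (TSV matrices + JSON manifest).

A bundle is a directory with one feature-by-sample TSV per modality (row
labels = feature IDs, column headers = sample IDs), optional per-modality
edge-list TSVs, an optional outcome TSV, and a ``manifest.json`` recording
names, families, dimensions, family parameters and provenance.  Sample IDs
must be identical and identically ordered across all files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .data import ModalityData, ValidationError
from .graph import FeatureGraph, load_graph

__all__ = ["write_bundle", "read_bundle", "write_truth", "read_truth"]

_FLOAT_FMT = "%.10g"


def write_bundle(
    modalities: List[ModalityData],
    Y: Optional[np.ndarray],
    graph: Optional[FeatureGraph],
    path,
    seed: Optional[int] = None,
    extra: Optional[dict] = None,
) -> Path:
    """Write a dataset bundle; returns the bundle directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    n = modalities[0].n
    sample_ids = [f"s{i}" for i in range(n)]
    manifest: dict = {"format": "sgbfa-bundle-v1", "n": n, "modalities": []}
    if seed is not None:
        manifest["seed"] = int(seed)
    for mod in modalities:
        fname = f"{mod.name}.tsv"
        df = pd.DataFrame(mod.X, index=list(mod.feature_ids),
                          columns=sample_ids)
        df.to_csv(path / fname, sep="\t", float_format=_FLOAT_FMT)
        entry = {
            "name": mod.name,
            "family": mod.family,
            "p": mod.p,
            "file": fname,
        }
        if mod.trials is not None:
            entry["trials"] = [int(v) for v in mod.trials]
        if mod.failures is not None:
            entry["failures"] = [float(v) for v in mod.failures]
        manifest["modalities"].append(entry)
    if Y is not None:
        ydf = pd.DataFrame(
            np.atleast_2d(Y),
            index=[f"y{j}" for j in range(np.atleast_2d(Y).shape[0])],
            columns=sample_ids,
        )
        ydf.to_csv(path / "outcomes.tsv", sep="\t", float_format=_FLOAT_FMT)
        manifest["outcomes"] = "outcomes.tsv"
    if graph is not None:
        graph_files = {}
        for name in graph.modality_names:
            ids = graph.feature_ids[name]
            rows = sorted(
                (ids[i], ids[j]) for (i, j) in graph.edges[name]
            )
            gname = f"graph_{name}.tsv"
            with open(path / gname, "w") as fh:
                fh.write("feature_id_1\tfeature_id_2\n")
                for a, b in rows:
                    fh.write(f"{a}\t{b}\n")
            graph_files[name] = gname
        manifest["graphs"] = graph_files
    if extra:
        manifest["extra"] = extra
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_bundle(path) -> Tuple[List[ModalityData], Optional[np.ndarray],
                               Optional[FeatureGraph]]:
    """Read and validate a dataset bundle."""
    path = Path(path)
    mpath = path / "manifest.json"
    if not mpath.exists():
        raise ValidationError(f"no manifest.json in {path}")
    with open(mpath) as fh:
        manifest = json.load(fh)
    modalities: List[ModalityData] = []
    sample_ids: Optional[List[str]] = None
    for entry in manifest["modalities"]:
        fpath = path / entry["file"]
        df = pd.read_csv(fpath, sep="\t", index_col=0)
        if sample_ids is None:
            sample_ids = list(df.columns)
        elif list(df.columns) != sample_ids:
            raise ValidationError(
                f"{fpath}: sample IDs differ from previous modality files"
            )
        if df.shape[0] != entry["p"]:
            raise ValidationError(
                f"{fpath}: {df.shape[0]} rows but manifest says p={entry['p']}"
            )
        family = entry["family"]
        if family not in ("gaussian", "binomial", "negative_binomial"):
            raise ValidationError(
                f"{fpath}: unknown family {family!r} in manifest"
            )
        modalities.append(ModalityData(
            name=entry["name"],
            X=df.to_numpy(dtype=float),
            family=family,
            trials=np.asarray(entry["trials"], dtype=int)
            if "trials" in entry else None,
            failures=np.asarray(entry["failures"], dtype=float)
            if "failures" in entry else None,
            feature_ids=[str(i) for i in df.index],
        ))
    Y = None
    if "outcomes" in manifest:
        opath = path / manifest["outcomes"]
        if not opath.exists():
            raise ValidationError(f"manifest names outcome file {opath} "
                                  "but it does not exist")
        ydf = pd.read_csv(opath, sep="\t", index_col=0)
        if list(ydf.columns) != sample_ids:
            raise ValidationError(f"{opath}: sample IDs differ from modality "
                                  "files")
        Y = ydf.to_numpy(dtype=float)
    graph = None
    if "graphs" in manifest:
        edge_lists = {}
        for name, gname in manifest["graphs"].items():
            gdf = pd.read_csv(path / gname, sep="\t")
            edge_lists[name] = list(
                zip(gdf.iloc[:, 0].astype(str), gdf.iloc[:, 1].astype(str))
            )
        graph = load_graph(edge_lists, modalities)
    return modalities, Y, graph


def write_truth(sim, path) -> Path:
    """Write ground-truth matrices of a simulated scenario (for evaluation)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savetxt(path / "W_true.tsv", sim.W, delimiter="\t", fmt=_FLOAT_FMT)
    np.savetxt(path / "Z_true.tsv", sim.Z, delimiter="\t", fmt=_FLOAT_FMT)
    np.savetxt(path / "m_true.tsv", sim.m[None], delimiter="\t",
               fmt=_FLOAT_FMT)
    np.savetxt(path / "mu_true.tsv", sim.mu, delimiter="\t", fmt=_FLOAT_FMT)
    np.savetxt(path / "mask_true.tsv", sim.mask.astype(int), delimiter="\t",
               fmt="%d")
    if sim.B is not None:
        np.savetxt(path / "B_true.tsv", sim.B, delimiter="\t",
                   fmt=_FLOAT_FMT)
    return path


def read_truth(path) -> dict:
    path = Path(path)
    out = {
        "W": np.loadtxt(path / "W_true.tsv", delimiter="\t", ndmin=2),
        "Z": np.loadtxt(path / "Z_true.tsv", delimiter="\t", ndmin=2),
        "m": np.loadtxt(path / "m_true.tsv", delimiter="\t", ndmin=2)[0],
        "mu": np.loadtxt(path / "mu_true.tsv", delimiter="\t", ndmin=2),
        "mask": np.loadtxt(path / "mask_true.tsv", delimiter="\t",
                           ndmin=2).astype(bool),
    }
    bpath = path / "B_true.tsv"
    if bpath.exists():
        out["B"] = np.loadtxt(bpath, delimiter="\t", ndmin=2)
    return out
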