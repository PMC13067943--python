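"""Readers and writers for the pipeline's delimited and sparse formats.

Delimited tables are tab-separated with an optional metadata header of
``# key: value`` comment lines (seed and provenance are always recorded
there by the writers).  Count matrices use Matrix Market triplets (genes x
cells, 1-based indices on disk, 0-based in memory) with ``genes.tsv`` /
``barcodes.tsv`` sidecars, the usual droplet-pipeline layout.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from anndata import AnnData
from scipy import io as spio
from scipy import sparse


def write_table(df: pd.DataFrame, path: str | Path,
                metadata: Mapping | None = None, sep: str = "\t") -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {json.dumps(val)}\n")
        df.to_csv(fh, sep=sep, index=False)


def read_table(path: str | Path, sep: str = "\t") -> tuple[pd.DataFrame, dict]:
    """Read a delimited table, returning (frame, metadata).  Mixed line
    endings are tolerated; malformed metadata lines raise with the line
    number."""
    path = Path(path)
    metadata: dict = {}
    with path.open("r", newline=None) as fh:
        lines = fh.read().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        try:
            key, val = line[1:].split(":", 1)
            metadata[key.strip()] = json.loads(val.strip())
        except (ValueError, json.JSONDecodeError) as err:
            raise ValueError(f"{path}:{i + 1}: malformed metadata line") from err
    else:
        body_start = len(lines)
    from io import StringIO
    df = pd.read_csv(StringIO("\n".join(lines[body_start:])), sep=sep)
    return df, metadata


def write_mtx(adata: AnnData, outdir: str | Path) -> None:
    """Write genes x cells Matrix Market triplets with sidecars (1-based
    indices on disk).  Gene annotation columns present in ``var`` are
    carried in genes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    mat = (X.T if sparse.issparse(X) else sparse.csr_matrix(X).T).tocoo()
    spio.mmwrite(outdir / "matrix.mtx", mat, field="integer")
    var = adata.var.reset_index()
    var.columns = ["gene"] + list(var.columns[1:])
    var.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    pd.Series(adata.obs_names, name="barcode").to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False)


def read_mtx(indir: str | Path) -> AnnData:
    """Read the triplet layout back into a cells x genes AnnData (0-based in
    memory)."""
    indir = Path(indir)
    try:
        mat = spio.mmread(indir / "matrix.mtx")
    except ValueError as err:
        raise ValueError(f"{indir / 'matrix.mtx'}: malformed Matrix Market "
                         f"file: {err}") from err
    genes = pd.read_csv(indir / "genes.tsv", sep="\t").set_index("gene")
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t")["barcode"]
    X = sparse.csr_matrix(mat.T.astype(np.int32))
    if X.shape != (len(barcodes), len(genes)):
        raise ValueError("matrix dimensions do not match sidecar files")
    return AnnData(X=X, obs=pd.DataFrame(index=barcodes.astype(str)),
                   var=genes)


def write_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    annot.reset_index().to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "start"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation requires columns {sorted(required)}")
    return df.set_index("gene")


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text) or {}
    if path.suffix == ".json":
        return json.loads(text)
    raise ValueError(f"unsupported config format: {path.suffix!r}")


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
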