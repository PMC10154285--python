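"""Readers and writers for the plain-text formats the CLI consumes.

Expression matrices are genes x cells, either TSV (first column gene ids,
header row of cell ids) or MatrixMarket ``.mtx`` with companion gene/cell
id files.  Counts are raw molecule-count estimates; nothing is normalized
internally (normalization would destroy the meaning of the VMR).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from fanoreg.chains import BirthDeathChain, NetworkChain
from fanoreg.grn import GRNStatus
from fanoreg.inference import Call, ExpressionMatrix, GeneCall, InferenceReport
from fanoreg.vmrstats import VMRFlag, VMRResult

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "write_report",
    "read_report",
    "write_truth",
    "read_truth",
    "load_model_spec",
]

REPORT_COLUMNS = [
    "gene", "n", "mean", "var", "vmr", "ci_low", "ci_high", "p",
    "grn_status", "call", "caveats",
]


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def _sidecar(path: Path, kind: str) -> Path:
    return path.with_name(path.stem + f"_{kind}.txt")


def read_expression_matrix(
    path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read a genes x cells matrix from TSV or MatrixMarket.

    For ``.mtx`` input the gene and cell identifiers are read from companion
    files (default ``<stem>_genes.txt`` / ``<stem>_cells.txt``, one id per
    line).  ``transpose=True`` accepts a cells x genes orientation.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        raw = mmread(path)
        mat = raw.toarray() if hasattr(raw, "toarray") else np.asarray(raw)
        genes_path = Path(genes_path) if genes_path else _sidecar(path, "genes")
        cells_path = Path(cells_path) if cells_path else _sidecar(path, "cells")
        genes = genes_path.read_text().split()
        cells = cells_path.read_text().split()
        if transpose:
            mat = mat.T
        if mat.shape != (len(genes), len(cells)):
            raise ValueError(
                f"{path}: matrix shape {mat.shape} does not match "
                f"{len(genes)} gene ids and {len(cells)} cell ids"
            )
        return ExpressionMatrix(genes=tuple(genes), cells=tuple(cells), counts=mat)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if transpose:
        df = df.T
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ids {dupes[:5]}")
    return ExpressionMatrix(
        genes=tuple(str(g) for g in df.index),
        cells=tuple(str(c) for c in df.columns),
        counts=df.to_numpy(),
    )


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV, or as MTX (+ id sidecars) if path ends in .mtx."""
    path = Path(path)
    if path.suffix == ".mtx":
        mmwrite(str(path), csr_matrix(expr.counts))
        _sidecar(path, "genes").write_text("\n".join(expr.genes) + "\n")
        _sidecar(path, "cells").write_text("\n".join(expr.cells) + "\n")
        return
    df = pd.DataFrame(expr.counts, index=list(expr.genes), columns=list(expr.cells))
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# inference reports
# ---------------------------------------------------------------------------


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n")


def _unescape(text: str) -> str:
    out = []
    it = iter(range(len(text)))
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "\\" and i + 1 < len(text):
            nxt = text[i + 1]
            out.append({"t": "\t", "n": "\n", "\\": "\\"}.get(nxt, "\\" + nxt))
            i += 2
        else:
            out.append(ch)
            i += 1
    return "".join(out)


def write_report(
    report: InferenceReport,
    tsv_path: str | Path | None = None,
    json_path: str | Path | None = None,
) -> None:
    """Serialize a report as TSV (fixed column order) and/or a JSON mirror."""
    rows = []
    for gc in report.calls:
        rows.append(
            {
                "gene": gc.gene,
                "n": gc.vmr.n,
                "mean": gc.vmr.mean,
                "var": gc.vmr.var,
                "vmr": gc.vmr.vmr,
                "ci_low": gc.vmr.ci_low,
                "ci_high": gc.vmr.ci_high,
                "p": gc.vmr.p_value,
                "grn_status": gc.grn_status.value,
                "call": gc.call.value,
                "caveats": _escape("; ".join(gc.caveats)),
            }
        )
    if tsv_path is not None:
        df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
        df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = {
            "parameters": dict(report.parameters),
            "summary": report.summary,
            "calls": [
                {**row, "caveats": list(gc.caveats)}
                for row, gc in zip(rows, report.calls)
            ],
        }
        Path(json_path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


def read_report(tsv_path: str | Path) -> InferenceReport:
    """Re-parse a TSV report (round-trip partner of :func:`write_report`)."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"gene": str}, keep_default_na=False,
                     na_values=["nan", ""])
    calls = []
    for _, r in df.iterrows():
        vmr_value = float(r["vmr"])
        flag = VMRFlag.NOT_SIGNIFICANT
        if np.isnan(vmr_value):
            flag = VMRFlag.UNDEFINED
        elif vmr_value < float(r["ci_low"]):
            flag = VMRFlag.BELOW
        elif vmr_value > float(r["ci_high"]):
            flag = VMRFlag.ABOVE
        res = VMRResult(
            n=int(r["n"]), mean=float(r["mean"]), var=float(r["var"]), vmr=vmr_value,
            ci_low=float(r["ci_low"]), ci_high=float(r["ci_high"]),
            p_value=float(r["p"]), flag=flag,
        )
        raw_caveats = r["caveats"]
        if raw_caveats is None or (isinstance(raw_caveats, float) and np.isnan(raw_caveats)):
            caveats = ()
        else:
            caveats = tuple(c for c in _unescape(str(raw_caveats)).split("; ") if c)
        calls.append(
            GeneCall(
                gene=str(r["gene"]),
                vmr=res,
                grn_status=GRNStatus(r["grn_status"]),
                call=Call(r["call"]),
                caveats=caveats,
            )
        )
    return InferenceReport(calls=tuple(calls), parameters={})


# ---------------------------------------------------------------------------
# truth labels
# ---------------------------------------------------------------------------


def write_truth(truth: Mapping[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene\tlabel\n")
        for gene, label in truth.items():
            fh.write(f"{gene}\t{label}\n")


def read_truth(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["gene"], df["label"]))


# ---------------------------------------------------------------------------
# model specification files (JSON)
# ---------------------------------------------------------------------------


def _rate_fn(spec: Mapping[str, object]):
    """Compile one network rate specification into a function of the state."""
    family = spec.get("family")
    if family == "constant":
        v = float(spec["value"])
        return lambda n: v
    if family == "indicator":
        idx = int(spec["species"])
        eq = int(spec["equals"])
        v = float(spec.get("value", 1.0))
        return lambda n: v if n[idx] == eq else 0.0
    if family == "linear_in":
        idx = int(spec["species"])
        slope = float(spec.get("slope", 1.0))
        intercept = float(spec.get("intercept", 0.0))
        return lambda n: max(intercept + slope * n[idx], 0.0)
    raise ValueError(f"unknown network rate family {family!r}")


def load_model_spec(path: str | Path) -> BirthDeathChain | NetworkChain:
    """Load a model specification (JSON) into a chain object.

    ``type: birth_death`` supports families ``constant`` (f, g), ``linear``
    (k, b, c), ``hill`` (vmax, K, coef, g, baseline) or explicit arrays
    ``f``/``g``.  ``type: network`` takes per-species rate specs
    (``constant`` | ``indicator`` | ``linear_in``), a ``box`` and an
    ``initial_state``.
    """
    cfg = json.loads(Path(path).read_text())
    kind = cfg.get("type")
    if kind == "birth_death":
        n_max = cfg.get("n_max")
        family = cfg.get("family")
        if family == "constant":
            return BirthDeathChain.constant(cfg["f"], cfg["g"], n_max=n_max)
        if family == "linear":
            return BirthDeathChain.linear(cfg["k"], cfg["b"], cfg["c"], n_max=n_max)
        if family == "hill":
            return BirthDeathChain.hill(
                vmax=cfg["vmax"], K=cfg["K"], coef=cfg.get("coef", 2.0),
                g=cfg["g"], baseline=cfg.get("baseline", 0.0), n_max=n_max,
            )
        if family is None and "f" in cfg and "g" in cfg:
            return BirthDeathChain.from_arrays(cfg["f"], cfg["g"])
        raise ValueError(f"unknown birth_death family {family!r}")
    if kind == "network":
        species = cfg["species"]
        m = len(species)
        f = [_rate_fn(s["f"]) for s in species]
        g = [_rate_fn(s["g"]) for s in species]
        box = tuple(int(b) for b in cfg.get("box", [100] * m))
        init = tuple(int(x) for x in cfg.get("initial_state", [0] * m))
        return NetworkChain(m=m, f=f, g=g, box=box, initial_state=init)
    raise ValueError(f"unknown model type {kind!r}")
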