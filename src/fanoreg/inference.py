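"""Per-gene decision procedure combining VMR significance with GRN topology.

The decision logic, in order:

1. gene absent from the GRN or inside a feedback loop -> undetermined
   (cycle membership voids both routes);
2. self-loop declared in the GRN -> reported as declared, not inferred;
3. VMR significantly below 1 and the gene is acyclic in the GRN ->
   autoregulation (non-autonomous route: needs only constant unregulated
   degradation and the one-step model, so it takes precedence);
4. VMR significantly above 1, no ancestors, and the user asserts autonomous
   expression -> positive autoregulation (autonomy is unverifiable, so this
   route is opt-in and always caveated);
5. otherwise undetermined.

Negative statements ("no autoregulation") are never emitted: the method
cannot establish absence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from fanoreg.grn import GRN, GRNStatus, grn_status
from fanoreg.vmrstats import VMRFlag, VMRResult, vmr_test

__all__ = [
    "Call",
    "ExpressionMatrix",
    "GeneCall",
    "InferenceReport",
    "call_gene",
    "infer_autoregulation",
]


class Call(str, Enum):
    POSITIVE_PROP1 = "positive_autoregulation_prop1"
    AUTOREG_PROP2 = "autoregulation_prop2"
    UNDETERMINED = "undetermined"
    DECLARED = "declared_in_grn"


CAVEAT_PROP2 = (
    "constant unregulated degradation assumed",
    "one-step model assumed",
    "negative autoregulation if expression autonomous",
)
CAVEAT_PROP1 = ("autonomy unverifiable; less reliable",)


@dataclass(frozen=True)
class ExpressionMatrix:
    """genes x cells count matrix with ordered identifiers."""

    genes: tuple[str, ...]
    cells: tuple[str, ...]
    counts: np.ndarray
    non_integer: bool = False

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if counts.size and counts.min() < 0:
            i, j = np.unravel_index(int(np.argmin(counts)), counts.shape)
            raise ValueError(
                f"negative entry {counts[i, j]} at gene {self.genes[i]!r}, cell {self.cells[j]!r}"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers must be unique")
        non_int = bool(counts.size) and not np.allclose(counts, np.round(counts))
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "non_integer", non_int)

    @classmethod
    def from_counts(
        cls, counts: np.ndarray, genes: Sequence[str] | None = None, cells: Sequence[str] | None = None
    ) -> "ExpressionMatrix":
        counts = np.asarray(counts)
        g = tuple(genes) if genes is not None else tuple(f"gene{i}" for i in range(counts.shape[0]))
        c = tuple(cells) if cells is not None else tuple(f"cell{j}" for j in range(counts.shape[1]))
        return cls(genes=g, cells=c, counts=counts)

    def row(self, gene: str) -> np.ndarray:
        return self.counts[self.genes.index(gene)]


@dataclass(frozen=True)
class GeneCall:
    gene: str
    vmr: VMRResult
    grn_status: GRNStatus
    call: Call
    caveats: tuple[str, ...] = ()


@dataclass(frozen=True)
class InferenceReport:
    calls: tuple[GeneCall, ...]
    parameters: Mapping[str, object]

    @property
    def summary(self) -> dict[str, int]:
        out: dict[str, int] = {c.value: 0 for c in Call}
        for gc in self.calls:
            out[gc.call.value] += 1
        return out


def call_gene(vmr: VMRResult, status: GRNStatus, autonomous: bool) -> tuple[Call, tuple[str, ...]]:
    """Apply the decision order to one gene's test result and GRN status.

    Returns ``(call, caveats)``; assembly into a :class:`GeneCall` is left
    to the caller, which knows the gene id.
    """
    if not isinstance(status, GRNStatus):
        raise TypeError(f"status must be a GRNStatus, got {status!r}")
    caveats: tuple[str, ...] = ()
    if status in (GRNStatus.ABSENT, GRNStatus.IN_CYCLE):
        call = Call.UNDETERMINED
        if status is GRNStatus.ABSENT:
            caveats = ("gene not present in the supplied GRN",)
        else:
            caveats = ("gene lies on a feedback loop; neither route applies",)
    elif status is GRNStatus.SELF_LOOP_DECLARED:
        call = Call.DECLARED
        caveats = ("autoregulation declared in GRN; excluded from VMR-based inference",)
    elif vmr.flag is VMRFlag.BELOW:
        call = Call.AUTOREG_PROP2
        caveats = CAVEAT_PROP2
    elif vmr.flag is VMRFlag.ABOVE and status is GRNStatus.NO_ANCESTORS and autonomous:
        call = Call.POSITIVE_PROP1
        caveats = CAVEAT_PROP1
    else:
        call = Call.UNDETERMINED
        if vmr.flag is VMRFlag.ABOVE and status is GRNStatus.NO_ANCESTORS:
            caveats = ("VMR significantly above 1 but autonomy not asserted",)
        elif vmr.flag is VMRFlag.UNDEFINED:
            caveats = ("zero mean expression; VMR undefined",)
    return call, caveats


def infer_autoregulation(
    expr: ExpressionMatrix,
    grn: GRN,
    alpha: float = 0.05,
    autonomous: Iterable[str] = (),
) -> InferenceReport:
    """Run the full per-gene procedure over an expression matrix.

    ``autonomous`` is the (default empty) set of genes the user asserts to
    have autonomous expression, enabling the VMR > 1 route for them.
    """
    if len(expr.cells) < 2:
        raise ValueError("need at least 2 cells")
    if not expr.genes:
        raise ValueError("expression matrix has no genes")
    if expr.non_integer:
        warnings.warn(
            "expression matrix contains non-integer values; the theory concerns "
            "molecule counts -- convert indirect measurements before inference",
            RuntimeWarning,
            stacklevel=2,
        )
    autonomous = set(autonomous)
    calls = []
    for gene in expr.genes:
        res = vmr_test(expr.row(gene), alpha=alpha)
        status = grn_status(grn, gene)
        call, caveats = call_gene(res, status, gene in autonomous)
        calls.append(GeneCall(gene=gene, vmr=res, grn_status=status, call=call, caveats=caveats))
    params = {
        "alpha": alpha,
        "variance_estimator": "unbiased (n-1)",
        "test": "two-sided Gamma-null interval",
        "n_genes": len(expr.genes),
        "n_cells": len(expr.cells),
        "autonomous_asserted": sorted(autonomous),
        "software_version": _version(),
    }
    return InferenceReport(calls=tuple(calls), parameters=params)


def _version() -> str:
    from fanoreg import __version__

    return __version__
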