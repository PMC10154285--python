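# fanoreg

Infer gene **autoregulation** from single-cell, non-interventional, one-time
expression data using the **variance-to-mean ratio** (VMR / Fano factor) of
each gene, combined with the topology of a known gene regulatory network
(GRN).

The logic rests on two exact results about continuous-time Markov chain
models of gene expression:

1. **Autonomous route** — for a gene whose expression level is itself
   Markovian (synthesis rate `f_n`, per-molecule degradation `g_n`), a
   stationary VMR above 1 implies the relative growth rate `h_n = f_n/g_n`
   increases somewhere (positive autoregulation); a VMR below 1 implies it
   decreases somewhere (negative autoregulation); constant `h` gives a
   Poisson law with VMR exactly 1.
2. **Non-autonomous route** — in a one-step multi-species chain, a gene that
   is not in a feedback loop, has constant unregulated degradation, and no
   autoregulation must have VMR ≥ 1. Observing VMR significantly below 1
   therefore implies autoregulation (or failure of the one-step model).

Significance is assessed against the asymptotic null of the sample VMR for
Poisson data, `Gamma((n-1)/2, 2/(n-1))` (mean exactly 1). The method only
ever says "yes" or "cannot determine" — absence of autoregulation is never
claimed.

## What's in the box

| module | purpose |
| --- | --- |
| `fanoreg.chains` | exact stationary solvers: product-form recursion for birth-death chains, sparse `πQ = 0` solve on the reachable closed class for multi-species one-step networks; rate-level classification of autoregulation |
| `fanoreg.grn` | edge-list parsing, ancestors, feedback-loop membership, per-gene GRN status |
| `fanoreg.vmrstats` | sample VMR, Gamma-null interval/test, mixture VMR, intrinsic/extrinsic decomposition |
| `fanoreg.simulate` | exact Gillespie simulators (numba-accelerated): birth-death, networks, telegraph bursting, multi-stage cycle counterexample |
| `fanoreg.inference` | the per-gene decision procedure combining VMR flags with GRN status |
| `fanoreg.benchmark` | ground-truth-labelled synthetic benchmark generator |
| `fanoreg.evaluation` | hypergeometric random-classifier comparison, confusion tables |
| `fanoreg.io`, `fanoreg.cli` | TSV/MTX/JSON readers and writers, umbrella CLI |

## CLI

```bash
# per-gene autoregulation calls from a matrix (genes x cells TSV or MTX)
# and a two-column regulator->target edge list
fanoreg infer --expr matrix.tsv --grn edges.tsv --alpha 0.05 \
        --out report.tsv --json report.json

# just the VMR table with Gamma-null intervals
fanoreg vmr --expr matrix.tsv

# exact stationary distribution / marginal VMRs of a model spec (JSON)
fanoreg solve --model model.json

# exact SSA sample of a model spec
fanoreg simulate --model model.json --cells 5000 --seed 1 --out counts.tsv

# ground-truth-labelled synthetic benchmark + evaluation
fanoreg simulate-benchmark --cells 5000 --seed 1 --out-prefix bench
fanoreg infer --expr bench_matrix.tsv --grn bench_grn.tsv --out report.tsv
fanoreg evaluate --report report.tsv --truth bench_truth.tsv
```

Genes asserted to have autonomous expression (enabling the less reliable
VMR > 1 route) are listed one-per-line in a file passed via
`--autonomous`; by default that route is off.

Model spec files are JSON: `{"type": "birth_death", "family": "linear",
"k": 6, "b": -2, "c": 3}`, or `"family": "constant" | "hill"`, or explicit
`f`/`g` arrays; `"type": "network"` takes per-species rate specs
(`constant`, `indicator`, `linear_in`), a truncation `box` and an
`initial_state`.

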