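"""Frozen GMDH polynomial network used as a deterministic reference comparator.

A GMDH (group method of data handling) network composes two-input quadratic
nodes z = A·p² + B·q² + C·p·q + D·p + E·q + F.  The network evaluated here is
a fully specified, published three-layer comparator for the same breakthrough
problem; only evaluation is implemented — no GMDH self-organization or
training.  All coefficients are transcribed digit-for-digit as printed,
including two near-duplicate output-node variants whose cross-term signs
differ; the reproduction search evaluates both rather than resolving the
discrepancy.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diagnostics import compute_stats


@dataclass(frozen=True)
class PolyNode:
    """Two-input quadratic node z = A p² + B q² + C p q + D p + E q + F."""

    a: float  # p²
    b: float  # q²
    c: float  # p·q
    d: float  # p
    e: float  # q
    f: float  # constant
    p_input: int  # index into the upstream signal vector
    q_input: int

    def evaluate(self, p, q):
        p = np.asarray(p, float)
        q = np.asarray(q, float)
        return (
            self.a * p**2 + self.b * q**2 + self.c * p * q
            + self.d * p + self.e * q + self.f
        )


def eval_node(node: PolyNode, p: float, q: float) -> float:
    return float(node.evaluate(p, q))


# Printed coefficients.  Layer 1 acts on (x1, x2, x3, x4), layer 2 on
# (z1..z4), layer 3 on (w1..w3), the output node on (u1, u2).
_LAYER1 = (
    PolyNode(0.183, 0.149, 0.165, -0.242, -0.048, 0.678, 0, 1),    # z1(x1,x2)
    PolyNode(0.141, -1.6, -0.21, -0.028, 2.76, -0.167, 1, 3),      # z2(x2,x4)
    PolyNode(0.182, -1.606, -0.124, -0.075, 2.778, -0.167, 2, 3),  # z3(x3,x4)
    PolyNode(-0.002, -1.64, 0.172, -0.169, 2.684, -0.075, 0, 3),   # z4(x1,x4)
)
_LAYER2 = (
    PolyNode(-0.253, 0.248, -0.319, -0.05, 0.948, -0.044, 0, 1),   # w1(z1,z2)
    PolyNode(4.923, 0.234, -0.057, -5.738, 0.794, 1.676, 0, 2),    # w2(z1,z3)
    PolyNode(2.915, 0.237, -0.535, -2.733, 1.097, 0.577, 0, 3),    # w3(z1,z4)
)
_LAYER3 = (
    PolyNode(-0.802, -1.248, 1.972, 0.419, 0.666, -0.011, 0, 1),   # u1(w1,w2)
    PolyNode(1.433, 1.571, -3.077, 0.603, 0.48, -0.014, 1, 2),     # u2(w2,w3)
)
# Output node as printed (note the sign of the cross term and 1.24 vs the
# 1.248 of layer-3 node 1 — transcribed exactly, not "corrected").
_OUTPUT_PRINTED = PolyNode(-0.802, -1.24, -1.972, 0.419, 0.666, -0.011, 0, 1)
# Variant reusing the layer-3 node-1 coefficients, evaluated by the
# reproduction search alongside the printed form.
_OUTPUT_L3N1 = PolyNode(-0.802, -1.248, 1.972, 0.419, 0.666, -0.011, 0, 1)


@dataclass(frozen=True)
class GMDHNetwork:
    """Three quadratic layers plus an output node, with frozen wiring."""

    layer1: tuple[PolyNode, ...] = _LAYER1
    layer2: tuple[PolyNode, ...] = _LAYER2
    layer3: tuple[PolyNode, ...] = _LAYER3
    output: PolyNode = _OUTPUT_PRINTED

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Propagate rows of X (4 columns, order x1..x4) through the network."""
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != 4:
            raise ValueError(f"GMDH network expects 4 input columns, got {X.shape[1]}")
        signals = [X[:, i] for i in range(4)]
        for layer in (self.layer1, self.layer2, self.layer3):
            signals = [n.evaluate(signals[n.p_input], signals[n.q_input]) for n in layer]
        return self.output.evaluate(signals[self.output.p_input], signals[self.output.q_input])

    def to_dict(self) -> dict:
        def node(n: PolyNode) -> dict:
            return {"a": n.a, "b": n.b, "c": n.c, "d": n.d, "e": n.e, "f": n.f,
                    "p_input": n.p_input, "q_input": n.q_input}
        return {
            "layer1": [node(n) for n in self.layer1],
            "layer2": [node(n) for n in self.layer2],
            "layer3": [node(n) for n in self.layer3],
            "output": node(self.output),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def predict_gmdh(network: GMDHNetwork, X: np.ndarray) -> np.ndarray:
    return network.predict(X)


def default_network(output_variant: str = "printed") -> GMDHNetwork:
    if output_variant == "printed":
        return GMDHNetwork()
    if output_variant == "l3n1":
        return GMDHNetwork(output=_OUTPUT_L3N1)
    raise ValueError(f"unknown output variant {output_variant!r}")


def reproduction_search(
    X_normalized: np.ndarray,
    X_raw: np.ndarray,
    observed: np.ndarray,
    top: int | None = None,
) -> pd.DataFrame:
    """Search input conventions for the best match of the frozen network.

    The published network never maps x1..x4 to physical variables, so this
    evaluates all 24 column permutations × {normalized, raw} scaling ×
    {printed, l3n1} output variants and ranks them by %AAD against the
    observed ratios.  The caller documents which convention (if any)
    reproduces the published comparator statistics.
    """
    rows = []
    for scaling, X in (("normalized", X_normalized), ("raw", X_raw)):
        for perm in itertools.permutations(range(4)):
            Xp = X[:, perm]
            for variant in ("printed", "l3n1"):
                pred = default_network(variant).predict(Xp)
                s = compute_stats(pred, observed, label=f"{scaling}/{perm}/{variant}")
                rows.append({
                    "scaling": scaling,
                    "permutation": "".join(str(i + 1) for i in perm),
                    "output_variant": variant,
                    "aad_percent": s.aad_percent,
                    "r2": s.r2,
                    "mse": s.mse,
                    "std_resid": s.std_resid,
                })
    report = pd.DataFrame(rows).sort_values("aad_percent").reset_index(drop=True)
    return report.head(top) if top else report
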