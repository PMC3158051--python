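"""Null-model simulation: premeiotic territories placed uniformly at random.

In premeiotic nuclei with no pairing mechanism acting, homologous and
heterologous territory pairs are exchangeable, so their proximity-category
distributions must be statistically indistinguishable.  This module
simulates that null — whole premeiotic gonad fields of compact territories
placed uniformly inside the nuclear sphere — and returns one chi-square
p-value per simulated gonad.  Under the null those p-values are
approximately uniform on [0, 1]; a pairing signal would skew them low.

Distances here are computed analytically from the generated tube geometry
(no rendering), which is the same quantity the image route estimates and is
exact by construction.
"""

from __future__ import annotations

import numpy as np

from territory3d.paint import two_color_scheme
from territory3d.stats import chi_square_two_tailed
from territory3d.synth.nucleus import (
    NucleusSpec,
    PairSpec,
    generate_nucleus,
    planted_edge_distance,
)
from territory3d.topology import PROXIMITY_CATEGORIES, classify_proximity

__all__ = ["premeiotic_null_pvalues", "simulate_premeiotic_gonad_counts"]


def simulate_premeiotic_gonad_counts(n_nuclei: int = 91,
                                     seed: int = 0) -> np.ndarray:
    """Proximity-category counts (2 x 4: homologous / heterologous rows).

    Each nucleus carries two painted chromosome pairs (four compact
    territories) placed uniformly at random; the homologous distances are
    I-I and II-II, the heterologous ones the four I-II combinations, as in
    the two-paint premeiotic scoring design.
    """
    paints = [two_color_scheme("I", (0, 1)), two_color_scheme("II", (2, 3))]
    counts = np.zeros((2, len(PROXIMITY_CATEGORIES)), dtype=int)
    cat_index = {c: i for i, c in enumerate(PROXIMITY_CATEGORIES)}
    for k in range(n_nuclei):
        rng = np.random.default_rng([seed, k])
        nuc = NucleusSpec(pairs=[
            PairSpec(paint=p, stage_label="compact",
                     target_slenderness=1.5, bead_count=1)
            for p in paints
        ])
        generate_nucleus(nuc, rng)
        a1, a2 = nuc.territories["I"]
        b1, b2 = nuc.territories["II"]
        groups = [("hom", a1, a2), ("hom", b1, b2),
                  ("het", a1, b1), ("het", a1, b2),
                  ("het", a2, b1), ("het", a2, b2)]
        for kind, u, v in groups:
            d = planted_edge_distance(u, v, n_samples=80)
            scale = 0.5 * (u.width + v.width)
            cat = classify_proximity(d, scale, touching=d == 0.0)
            counts[0 if kind == "hom" else 1, cat_index[cat]] += 1
    return counts


def premeiotic_null_pvalues(n_gonads: int = 200, n_nuclei: int = 91,
                            seed: int = 0) -> np.ndarray:
    """One homolog-vs-heterolog chi-square p per simulated premeiotic gonad."""
    ps = []
    for g in range(n_gonads):
        counts = simulate_premeiotic_gonad_counts(
            n_nuclei=n_nuclei, seed=int(np.random.default_rng([seed, g]).integers(2**31)))
        keep = counts.sum(axis=0) > 0
        table = counts[:, keep]
        if table.shape[1] < 2 or table.sum(axis=1).min() == 0:
            continue
        ps.append(chi_square_two_tailed(table))
    return np.asarray(ps)
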