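"""Shared fixtures: toy LP networks, the brute-force vertex oracle and a
session-scoped core model."""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
import pytest

from egflux.model_core import Metabolite, Reaction, StoichiometricModel
from egflux.model_core import build_core_model


def make_toy_model(metabolites, reactions, objective_id) -> StoichiometricModel:
    """Assemble a small model from (id, compartment) and
    (id, stoich, lb, ub) tuples.  Formulas are left empty, so these toys
    are exempt from elemental balancing."""
    mets = {mid: Metabolite(mid, mid, comp) for mid, comp in metabolites}
    rxns = {rid: Reaction(rid, rid, dict(st), lb, ub)
            for rid, st, lb, ub in reactions}
    return StoichiometricModel(mets, rxns, objective_id)


@pytest.fixture(scope="session")
def core_model():
    return build_core_model(("NAD", "NADP"))


@pytest.fixture(scope="session")
def core_model_full():
    return build_core_model(("NAD", "NADP"), xylulose1p_route=True,
                            glyoxylate_secretion=True)


@pytest.fixture
def toy_chain():
    """Linear chain: uptake (cap 10) -> transport -> biomass. The LP
    optimum is the uptake capacity."""
    return make_toy_model(
        [("a_e", "e"), ("a_c", "c")],
        [("EX_a", {"a_e": -1}, -10, 0),
         ("T_a", {"a_e": -1, "a_c": 1}, 0, 1000),
         ("BIO", {"a_c": -1}, 0, 1000)],
        "BIO")


@pytest.fixture
def toy_diamond():
    """A -> B directly or via C; equal capacities.  Parsimony must put
    all flux on the one-step route."""
    return make_toy_model(
        [("a_e", "e"), ("a_c", "c"), ("b_c", "c"), ("c_c", "c")],
        [("EX_a", {"a_e": -1}, -10, 0),
         ("T_a", {"a_e": -1, "a_c": 1}, 0, 1000),
         ("DIRECT", {"a_c": -1, "b_c": 1}, 0, 1000),
         ("VIA1", {"a_c": -1, "c_c": 1}, 0, 1000),
         ("VIA2", {"c_c": -1, "b_c": 1}, 0, 1000),
         ("BIO", {"b_c": -1}, 0, 1000)],
        "BIO")


@pytest.fixture
def toy_parallel():
    """Two equivalent parallel routes feeding one demand of at most 10."""
    return make_toy_model(
        [("a_e", "e"), ("a_c", "c"), ("b_c", "c")],
        [("EX_a", {"a_e": -1}, -10, 0),
         ("T_a", {"a_e": -1, "a_c": 1}, 0, 1000),
         ("R1", {"a_c": -1, "b_c": 1}, 0, 1000),
         ("R2", {"a_c": -1, "b_c": 1}, 0, 1000),
         ("BIO", {"b_c": -1}, 0, 1000)],
        "BIO")


def enumerate_polytope_vertices(S: np.ndarray, lb: np.ndarray,
                                ub: np.ndarray, tol: float = 1e-9):
    """Exhaustively enumerate the vertices of {v : S v = 0, lb <= v <= ub}.

    A vertex has n linearly independent active constraints; the S rows
    contribute rank(S), so n - rank(S) coordinates sit at a bound.  All
    such combinations are tried by brute force — only viable for tiny
    networks (n <= 6 or so).
    """
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S) if S.size else 0
    nfree = n - rank
    vertices = []
    for fixed_idx in combinations(range(n), nfree):
        free_idx = [j for j in range(n) if j not in fixed_idx]
        for values in product(*[(lb[j], ub[j]) for j in fixed_idx]):
            rhs = -S[:, list(fixed_idx)] @ np.asarray(values) if fixed_idx \
                else np.zeros(S.shape[0])
            A = S[:, free_idx]
            sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            v = np.empty(n)
            v[list(fixed_idx)] = values
            v[free_idx] = sol
            if np.max(np.abs(S @ v)) > 1e-7:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            vertices.append(np.clip(v, lb, ub))
    # deduplicate
    unique = []
    for v in vertices:
        if not any(np.allclose(v, u, atol=1e-7) for u in unique):
            unique.append(v)
    return unique


@pytest.fixture(scope="session")
def vertex_oracle():
    return enumerate_polytope_vertices
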