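"""Animal-model BLUP via Henderson's mixed-model equations.

The milk-yield animal model is

    y = Xb + x·β + Zu + e,   var(u) = A·σa²,  var(e) = I·σe²,

with fixed factors (lactation-day class, lactation number, birth year,
milking times), one continuous covariate with coefficient β, and a
random additive genetic effect u structured by the pedigree numerator
relationship matrix A (tabular method).  The MME are solved with a
sum-to-zero constraint per fixed factor and variance ratio
λ = σe²/σa² = (1 − h²)/h²; solutions are the "estimated values"
(estimated breeding values) used to rank animals for production.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Pedigree:
    """Parent links; ``"0"`` marks an unknown parent."""

    animals: list[str]
    sire: dict[str, str]
    dam: dict[str, str]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        return cls(
            animals=list(df["animal"].astype(str)),
            sire=dict(zip(df["animal"].astype(str), df["sire"].astype(str))),
            dam=dict(zip(df["animal"].astype(str), df["dam"].astype(str))),
        )

    @classmethod
    def read_tsv(cls, path) -> "Pedigree":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["animal", "sire", "dam"], dtype=str,
                         comment="#")
        return cls.from_frame(df)

    def topological_order(self) -> list[str]:
        """Parents-before-offspring order; raises on a pedigree cycle."""
        known = set(self.animals)
        state: dict[str, int] = {}
        order: list[str] = []

        def visit(a: str) -> None:
            if state.get(a) == 2:
                return
            if state.get(a) == 1:
                raise ValueError(f"pedigree cycle involving {a!r}")
            state[a] = 1
            for parent in (self.sire.get(a, "0"), self.dam.get(a, "0")):
                if parent != "0" and parent in known:
                    visit(parent)
            state[a] = 2
            order.append(a)

        for a in self.animals:
            visit(a)
        return order


def build_a_matrix(ped: Pedigree):
    """Numerator relationship matrix by the tabular method.

    Returns ``(A, order)`` where ``order`` is the topological animal
    order indexing the rows/columns of the symmetric PSD matrix A.
    """
    order = ped.topological_order()
    index = {a: i for i, a in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for i, animal in enumerate(order):
        s = ped.sire.get(animal, "0")
        d = ped.dam.get(animal, "0")
        si = index.get(s) if s != "0" else None
        di = index.get(d) if d != "0" else None
        A[i, i] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None
                         else 0.0)
        for j in range(i):
            val = 0.0
            if si is not None:
                val += 0.5 * A[j, si]
            if di is not None:
                val += 0.5 * A[j, di]
            A[i, j] = A[j, i] = val
    return A, order


@dataclass
class MMEResult:
    """Solutions of the mixed-model equations."""

    intercept: float
    fixed_effects: dict[str, dict] = field(default_factory=dict)
    beta: float | None = None
    breeding_values: dict[str, float] = field(default_factory=dict)
    lam: float = 1.0
    constraint: str = "sum-to-zero per factor"


def _sum_to_zero_design(levels: np.ndarray):
    """Effects-coding design for one factor: L−1 columns, last level = −Σ."""
    uniq = sorted(pd.unique(levels).tolist())
    L = len(uniq)
    idx = {lev: i for i, lev in enumerate(uniq)}
    codes = np.array([idx[v] for v in levels])
    X = np.zeros((len(levels), max(L - 1, 0)))
    for col in range(L - 1):
        X[codes == col, col] = 1.0
    X[codes == L - 1, :] = -1.0
    return X, uniq


def solve_animal_model(
    ped: Pedigree,
    y: np.ndarray,
    fixed_factors: pd.DataFrame,
    covariate: np.ndarray | None,
    animal_ids: list[str],
    h2: float,
) -> MMEResult:
    """Solve Henderson's MME for the single-trait animal model.

    Parameters
    ----------
    ped : Pedigree
        Every phenotyped animal must appear in it.
    y : array
        Phenotype records, one per row of ``fixed_factors``.
    fixed_factors : DataFrame
        One categorical column per fixed factor (levels of A_i).
    covariate : array or None
        Single continuous regressor x (coefficient β), if present.
    animal_ids : list of str
        Animal of each record (links records to the pedigree).
    h2 : float
        Heritability; λ = (1 − h²)/h².
    """
    if not (0.0 < h2 < 1.0):
        raise ValueError("h2 must be in (0, 1)")
    y = np.asarray(y, dtype=float)
    n_rec = y.size
    missing = [a for a in animal_ids if a not in set(ped.animals)]
    if missing:
        raise ValueError(f"phenotyped animals absent from pedigree: "
                         f"{missing[:5]}")

    A, order = build_a_matrix(ped)
    a_index = {a: i for i, a in enumerate(order)}
    n_anim = len(order)
    lam = (1.0 - h2) / h2

    # fixed design: intercept + sum-to-zero coded factors + covariate
    blocks = [np.ones((n_rec, 1))]
    factor_levels: dict[str, list] = {}
    for col in fixed_factors.columns:
        Xf, uniq = _sum_to_zero_design(fixed_factors[col].to_numpy())
        blocks.append(Xf)
        factor_levels[col] = uniq
    has_cov = covariate is not None
    if has_cov:
        blocks.append(np.asarray(covariate, dtype=float).reshape(-1, 1))
    W = np.hstack(blocks)

    Z = np.zeros((n_rec, n_anim))
    for r, a in enumerate(animal_ids):
        Z[r, a_index[a]] = 1.0

    Ainv = np.linalg.inv(A)
    C = np.block([
        [W.T @ W, W.T @ Z],
        [Z.T @ W, Z.T @ Z + lam * Ainv],
    ])
    rhs = np.concatenate([W.T @ y, Z.T @ y])
    try:
        sol = np.linalg.solve(C, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular mixed-model equations after constraints; check for "
            f"confounded fixed-effect levels in {list(fixed_factors.columns)}"
        ) from exc
    resid = np.linalg.norm(C @ sol - rhs)
    scale = max(np.linalg.norm(rhs), 1.0)
    if resid / scale > 1e-8:
        raise ValueError(f"MME solve did not converge (residual {resid:.3g})")

    # unpack
    pos = 1
    fixed: dict[str, dict] = {}
    for col in fixed_factors.columns:
        uniq = factor_levels[col]
        L = len(uniq)
        theta = sol[pos:pos + L - 1]
        effects = {lev: float(t) for lev, t in zip(uniq[:-1], theta)}
        effects[uniq[-1]] = float(-theta.sum())
        fixed[col] = effects
        pos += L - 1
    beta = float(sol[pos]) if has_cov else None
    if has_cov:
        pos += 1
    u = sol[pos:pos + n_anim]
    return MMEResult(
        intercept=float(sol[0]),
        fixed_effects=fixed,
        beta=beta,
        breeding_values={a: float(v) for a, v in zip(order, u)},
        lam=lam,
    )
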