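"""Cooperative ligand-on-lattice binding analysis for HU–DNA EMSA data.

An HU dimer occludes ``n`` base pairs of a ``N``-bp DNA lattice; binding is
described by the intrinsic association constant ``K`` (1/M) and a
nearest-neighbour cooperativity ``omega`` (McGhee–von Hippel convention:
relative affinity for a site contiguous to an already bound ligand versus
an isolated site; omega < 1 negative, omega > 1 positive cooperativity).

The finite lattice is treated exactly: a configuration with k bound
ligands and j immediately adjacent ligand pairs has statistical weight
(K L)^k omega^j, and the partition function is evaluated by a linear
recursion in O(N kmax).  The infinite-lattice McGhee–von Hippel closed
form is provided as a cross-check and as the classical binding-density
isotherm.  On top sit ligand-depletion-corrected free-ligand solving,
(K, omega) titration fitting, integer site-size estimation from
complex-count ladders, depletion-corrected single-site Kd fitting, and
dsDNA-normalised affinity profiles.

Concentrations are molar throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger("huihf.binding")


# ---------------------------------------------------------------------------
# model and distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatticeBindingModel:
    """Non-overlapping n-bp ligands on an N-bp lattice with
    nearest-neighbour contact cooperativity."""
    n: int          # site size, bp covered per bound dimer
    K: float        # intrinsic association constant, 1/M
    omega: float    # cooperativity, dimensionless
    N: int          # lattice length, bp

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("site size n must be >= 1")
        if self.N < self.n:
            raise ValueError("lattice length N must be >= n")
        if self.K <= 0 or self.omega <= 0:
            raise ValueError("K and omega must be positive")

    @property
    def kmax(self) -> int:
        return self.N // self.n


@dataclass
class OccupancyDistribution:
    p_k: np.ndarray     # probabilities for k = 0..kmax
    mean_k: float
    nu: float           # binding density, bound ligands per bp

    def __post_init__(self) -> None:
        self.p_k = np.asarray(self.p_k, dtype=float)
        if abs(self.p_k.sum() - 1.0) > 1e-12:
            raise ValueError("occupancy probabilities must sum to 1")
        if (self.p_k < -1e-15).any():
            raise ValueError("occupancy probabilities must be non-negative")


@dataclass
class EmsaTitration:
    """Quantified band fractions of one titration: rows follow
    ``protein_totals`` (dimer units, M), columns are complexes with
    k = 0, 1, ... bound dimers."""
    dna_label: str
    dna_length: int
    dna_total: float
    protein_totals: np.ndarray
    fractions: np.ndarray   # (len(protein_totals), kmax+1)

    def __post_init__(self) -> None:
        self.protein_totals = np.asarray(self.protein_totals, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape[0] != len(self.protein_totals):
            raise ValueError("one fraction row per protein concentration")
        if (self.protein_totals <= 0).any() or self.dna_total <= 0:
            raise ValueError("concentrations must be positive")
        rows = self.fractions.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 0.02):
            raise ValueError("band fractions per lane must sum to 1 +- 0.02")


@dataclass
class BindingFit:
    Kd: float
    Ka: float
    omega: float
    omega_ci: tuple[float, float] | None
    n: int
    rel_Ka: float | None = None
    rss: float | None = None
    bootstrap_seed: int | None = None

    def __post_init__(self) -> None:
        if self.Kd <= 0:
            raise ValueError("Kd must be positive")


@dataclass
class LadderExperiment:
    """Maximum resolvable complex count per duplex length, at fixed
    protein/DNA conditions."""
    entries: list[tuple[int, int]]   # (dna_length bp, max complex count)

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries)
        counts = [c for _, c in self.entries]
        if any(b < a for a, b in zip(counts, counts[1:])):
            raise ValueError("complex counts must be non-decreasing in length")


# ---------------------------------------------------------------------------
# exact finite-lattice statistics
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1024)
def _log_occupancy_coefficients(n: int, N: int, omega: float) -> np.ndarray:
    """log c_k, with c_k the sum over k-ligand configurations of
    omega^(adjacent pairs).

    The configuration weight (K L)^k omega^j factorises, so the partition
    function is the polynomial Z(x) = sum_k c_k x^k with x = K L; the c_k
    are computed once per (n, N, omega) by a left-to-right recursion over
    lattice positions that tracks whether a ligand ends exactly at the
    current position (to apply the contact factor), in O(N kmax).
    Log domain keeps long lattices (combinatorially large c_k) exact to
    float precision.
    """
    kmax = N // n
    logw = math.log(omega)
    # f0[i][k]: configurations of the first i positions with k ligands and
    # no ligand ending at i; f1[i][k]: a ligand ends exactly at i.
    f0 = np.full((N + 1, kmax + 1), -np.inf)
    f1 = np.full((N + 1, kmax + 1), -np.inf)
    f0[0, 0] = 0.0
    for i in range(1, N + 1):
        f0[i] = np.logaddexp(f0[i - 1], f1[i - 1])
        if i >= n:
            f1[i, 1:] = np.logaddexp(f0[i - n, :-1], logw + f1[i - n, :-1])
    out = np.logaddexp(f0[N], f1[N])
    out.setflags(write=False)
    return out


def lattice_partition(
    model: LatticeBindingModel, L_free: float
) -> OccupancyDistribution:
    """Exact equilibrium occupancy distribution on the finite lattice.

    Configuration weight: (K L)^k * omega^(number of immediately adjacent
    ligand pairs), summed exactly over all placements of non-overlapping
    n-bp ligands.
    """
    if L_free < 0:
        raise ValueError("free ligand concentration must be >= 0")
    x = model.K * L_free
    kmax = model.kmax
    if x == 0.0:
        p = np.zeros(kmax + 1)
        p[0] = 1.0
        return OccupancyDistribution(p_k=p, mean_k=0.0, nu=0.0)
    logc = _log_occupancy_coefficients(model.n, model.N, model.omega)
    logw = logc + np.arange(kmax + 1) * math.log(x)
    p = np.exp(logw - logw.max())
    p /= p.sum()
    mean_k = float((np.arange(kmax + 1) * p).sum())
    return OccupancyDistribution(p_k=p, mean_k=mean_k, nu=mean_k / model.N)


def mean_occupancy(model: LatticeBindingModel, L_free: float) -> float:
    return lattice_partition(model, L_free).mean_k


# ---------------------------------------------------------------------------
# infinite-lattice closed form (McGhee-von Hippel)
# ---------------------------------------------------------------------------

def _mvh_rhs(nu: float, K: float, n: int, omega: float) -> float:
    """Right-hand side Phi(nu) of the cooperative isotherm nu = L * Phi(nu)."""
    one_m_n = 1.0 - n * nu
    if one_m_n <= 0.0:
        return 0.0
    if abs(omega - 1.0) < 1e-9:
        if n == 1:
            return K * one_m_n
        return K * one_m_n * (one_m_n / (1.0 - (n - 1) * nu)) ** (n - 1)
    R = math.sqrt((1.0 - (n + 1) * nu) ** 2 + 4.0 * omega * nu * one_m_n)
    t1 = ((2.0 * omega - 1.0) * one_m_n + nu - R) / (
        2.0 * (omega - 1.0) * one_m_n
    )
    t2 = (1.0 - (n + 1) * nu + R) / (2.0 * one_m_n)
    return K * one_m_n * t1 ** (n - 1) * t2 ** 2


def mvh_density(K: float, n: int, omega: float, L_free: float) -> float:
    """Binding density nu (ligands per bp) from the infinite-lattice
    cooperative McGhee–von Hippel isotherm, solved by bracketed
    root-finding on [0, 1/n)."""
    if K <= 0 or omega <= 0 or n < 1:
        raise ValueError("invalid isotherm parameters")
    if L_free < 0:
        raise ValueError("free ligand concentration must be >= 0")
    if L_free == 0.0:
        return 0.0

    def g(nu: float) -> float:
        return nu - L_free * _mvh_rhs(nu, K, n, omega)

    lo, hi = 0.0, (1.0 - 1e-12) / n
    glo, ghi = g(lo), g(hi)
    if glo == 0.0:
        return 0.0
    if glo > 0 or ghi < 0:
        raise RuntimeError(
            f"no isotherm root in [0, 1/n): g(0)={glo:.3e}, g(1/n)={ghi:.3e} "
            f"(K={K}, n={n}, omega={omega}, L={L_free})"
        )
    nu = optimize.brentq(g, lo, hi, xtol=1e-16, rtol=1e-15, maxiter=200)
    if abs(g(nu)) > 1e-10:
        raise RuntimeError(f"isotherm residual too large: {g(nu):.3e}")
    return float(nu)


# ---------------------------------------------------------------------------
# mass conservation
# ---------------------------------------------------------------------------

def solve_free_ligand(
    model: LatticeBindingModel, dna_total: float, protein_total: float
) -> float:
    """Free ligand concentration under depletion: the unique L in
    [0, protein_total] with protein_total = L + dna_total * <k>(L)."""
    if dna_total < 0 or protein_total < 0:
        raise ValueError("totals must be >= 0")
    if protein_total == 0.0 or dna_total == 0.0:
        return protein_total

    def g(L: float) -> float:
        return L + dna_total * mean_occupancy(model, L) - protein_total

    # g is strictly increasing; g(0) = -P < 0, g(P) >= 0
    L = optimize.brentq(
        g, 0.0, protein_total, xtol=1e-300, rtol=8.9e-16, maxiter=300
    )
    return float(L)


def predicted_fractions(
    model: LatticeBindingModel,
    dna_total: float,
    protein_totals: np.ndarray,
    n_cols: int | None = None,
) -> np.ndarray:
    """Depletion-corrected occupancy distributions, one row per protein
    concentration.  If ``n_cols`` is smaller than kmax+1 the tail mass is
    aggregated into the last column (unresolved top band)."""
    rows = []
    for P in np.asarray(protein_totals, dtype=float):
        L = solve_free_ligand(model, dna_total, P)
        rows.append(lattice_partition(model, L).p_k)
    pred = np.stack(rows)
    if n_cols is not None:
        if n_cols < pred.shape[1]:
            head = pred[:, : n_cols - 1]
            tail = pred[:, n_cols - 1 :].sum(axis=1, keepdims=True)
            pred = np.hstack([head, tail])
        elif n_cols > pred.shape[1]:
            pad = np.zeros((pred.shape[0], n_cols - pred.shape[1]))
            pred = np.hstack([pred, pad])
    return pred


# ---------------------------------------------------------------------------
# titration fitting
# ---------------------------------------------------------------------------

def _fit_k_omega_once(
    t: EmsaTitration, n_fixed: int, fit_omega: bool, x0: np.ndarray
) -> tuple[float, float, float]:
    n_cols = t.fractions.shape[1]

    def residuals(theta: np.ndarray) -> np.ndarray:
        K = 10.0 ** theta[0]
        omega = 10.0 ** theta[1] if fit_omega else 1.0
        model = LatticeBindingModel(n=n_fixed, K=K, omega=omega, N=t.dna_length)
        pred = predicted_fractions(model, t.dna_total, t.protein_totals, n_cols)
        return (pred - t.fractions).ravel()

    if fit_omega:
        res = optimize.least_squares(
            residuals, x0, bounds=([0.0, -4.0], [15.0, 4.0]), xtol=1e-12,
            ftol=1e-12, gtol=1e-12,
        )
        K = 10.0 ** res.x[0]
        omega = 10.0 ** res.x[1]
    else:
        res = optimize.least_squares(
            residuals, x0[:1].tolist() + [0.0], bounds=([0.0, -1e-9], [15.0, 1e-9]),
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        K = 10.0 ** res.x[0]
        omega = 1.0
    return K, omega, float(np.sum(res.fun ** 2))


def fit_cooperative(
    t: EmsaTitration,
    n_fixed: int,
    fit_omega: bool = True,
    n_boot: int = 200,
    seed: int | None = None,
) -> BindingFit:
    """Least-squares (K, omega) from observed band fractions against the
    depletion-corrected finite-lattice model; omega confidence interval by
    parametric bootstrap (Gaussian residual noise, refit, 2.5/97.5
    percentiles)."""
    if len(t.protein_totals) < 4:
        raise ValueError("need >= 4 protein concentrations")
    bound = 1.0 - t.fractions[:, 0]
    if bound.max() < 0.05:
        raise ValueError("titration never leaves the free state: K not identifiable")
    if bound.min() > 0.95:
        raise ValueError("titration fully saturated: K not identifiable")

    x0 = np.array([math.log10(1.0 / np.median(t.protein_totals)), 0.0])
    K, omega, rss = _fit_k_omega_once(t, n_fixed, fit_omega, x0)

    ci = None
    if n_boot > 0 and fit_omega:
        rng = np.random.default_rng(seed)
        model = LatticeBindingModel(n=n_fixed, K=K, omega=omega, N=t.dna_length)
        pred = predicted_fractions(
            model, t.dna_total, t.protein_totals, t.fractions.shape[1]
        )
        sigma_obs = math.sqrt(rss / t.fractions.size)
        # The observation process truncates negative band fractions and
        # renormalises lanes, which shrinks raw quantification noise;
        # calibrate the raw sigma so simulated data reproduce the observed
        # residual spread (otherwise the bootstrap under-covers).
        shrink = []
        for _ in range(25):
            sim = np.clip(
                pred + rng.normal(0.0, sigma_obs, pred.shape), 0.0, None
            )
            sim /= sim.sum(axis=1, keepdims=True)
            shrink.append((sim - pred).std())
        sigma = sigma_obs / max(np.mean(shrink) / sigma_obs, 0.3)
        omegas = []
        x0b = np.array([math.log10(K), math.log10(omega)])
        for _ in range(n_boot):
            noisy = np.clip(pred + rng.normal(0.0, sigma, pred.shape), 0.0, None)
            noisy /= noisy.sum(axis=1, keepdims=True)
            tb = EmsaTitration(
                dna_label=t.dna_label, dna_length=t.dna_length,
                dna_total=t.dna_total, protein_totals=t.protein_totals,
                fractions=noisy,
            )
            try:
                _, ob, _ = _fit_k_omega_once(tb, n_fixed, True, x0b)
                omegas.append(ob)
            except Exception:  # pragma: no cover - rare numerical failure
                continue
        if omegas:
            ci = (
                float(np.percentile(omegas, 2.5)),
                float(np.percentile(omegas, 97.5)),
            )
    return BindingFit(
        Kd=1.0 / K, Ka=K, omega=omega, omega_ci=ci, n=n_fixed,
        rss=rss, bootstrap_seed=seed,
    )


# ---------------------------------------------------------------------------
# site-size estimation from ladders
# ---------------------------------------------------------------------------

@dataclass
class SiteSizeFit:
    n: int
    offset: int
    mismatches: int
    co_optimal: list[tuple[int, int]] = field(default_factory=list)


def estimate_site_size(
    ladder: LadderExperiment,
    n_range: tuple[int, int] = (4, 20),
    offset_slack: int = 2,
    offset_range: tuple[int, int] | None = None,
) -> SiteSizeFit:
    """Integer grid search for the site size from a complex-count ladder.

    Predicted maximum count: c(N) = 1 + floor((N - offset) / n), where the
    offset is the minimum duplex length accommodating the first dimer.
    Because that first dimer itself occludes n bp, the offset is
    constrained to n +- ``offset_slack`` bp (end breathing) unless an
    explicit ``offset_range`` is given; without this constraint a ladder
    showing a single count step cannot pin down n.  The (n, offset) pair
    minimising the number of mismatched lengths wins; ties break toward
    smaller n, then smaller offset.  All co-optimal pairs are reported.
    """
    counts = [c for _, c in ladder.entries]
    if len(ladder.entries) < 4:
        raise ValueError("need >= 4 ladder lengths")
    if len(set(counts)) < 2:
        raise ValueError("constant complex counts: site size not identifiable")

    results = []
    for n in range(n_range[0], n_range[1] + 1):
        if offset_range is None:
            offsets = range(max(0, n - offset_slack), n + offset_slack + 1)
        else:
            offsets = range(offset_range[0], offset_range[1] + 1)
        for off in offsets:
            mism = sum(
                1
                for (length, c) in ladder.entries
                if 1 + (length - off) // n != c
            )
            results.append((mism, n, off))
    results.sort()
    best_mism = results[0][0]
    co = [(n, off) for mism, n, off in results if mism == best_mism]
    n_best, off_best = co[0]
    return SiteSizeFit(
        n=n_best, offset=off_best, mismatches=best_mism, co_optimal=co
    )


# ---------------------------------------------------------------------------
# single-site Kd and affinity profiles
# ---------------------------------------------------------------------------

def bound_fraction_single_site(
    protein_total: np.ndarray, dna_total: float, Kd: float
) -> np.ndarray:
    """Fraction of DNA bound under 1:1 binding with ligand depletion:
    the complex concentration is the smaller root of
    C^2 - C (P + D + Kd) + P D = 0."""
    P = np.asarray(protein_total, dtype=float)
    b = P + dna_total + Kd
    C = (b - np.sqrt(b * b - 4.0 * P * dna_total)) / 2.0
    return C / dna_total


def fit_kd_single_site(
    protein_totals: Sequence[float],
    fraction_bound: Sequence[float],
    dna_total: float,
) -> float:
    """Depletion-corrected single-site Kd by least squares."""
    P = np.asarray(protein_totals, dtype=float)
    f = np.asarray(fraction_bound, dtype=float)
    if len(P) < 4:
        raise ValueError("need >= 4 titration points")
    if (f < 0).any() or (f > 1.02).any():
        raise ValueError("bound fractions must lie in [0, 1.02]")
    if f.min() > 0.95:
        raise ValueError("saturating data only: Kd not identifiable")

    def residuals(logkd: np.ndarray) -> np.ndarray:
        return bound_fraction_single_site(P, dna_total, 10.0 ** logkd[0]) - f

    # start at the protein concentration nearest half-saturation
    x0 = [math.log10(P[int(np.argmin(np.abs(f - 0.5)))])]
    res = optimize.least_squares(
        residuals, x0, bounds=([-15.0], [0.0]), xtol=1e-14, ftol=1e-14
    )
    return float(10.0 ** res.x[0])


def affinity_profile(fits: Mapping[str, BindingFit]) -> pd.DataFrame:
    """Association constants normalised to the same protein's dsDNA value.
    Requires a 'ds' reference entry; its rel_Ka is exactly 1."""
    if "ds" not in fits:
        raise ValueError("missing 'ds' reference entry")
    ka_ds = fits["ds"].Ka
    rows = []
    for label, fit in fits.items():
        rows.append(
            {
                "structure": label,
                "Kd": fit.Kd,
                "Ka": fit.Ka,
                "rel_Ka": 1.0 if label == "ds" else fit.Ka / ka_ds,
            }
        )
    return pd.DataFrame(rows).set_index("structure")


# ---------------------------------------------------------------------------
# titration table I/O
# ---------------------------------------------------------------------------

def read_titration_tsv(path) -> list[EmsaTitration]:
    """Read titrations from TSV with columns dna_label, dna_length,
    dna_total_nM, protein_total_nM, frac_k0, frac_k1, ..."""
    df = pd.read_csv(path, sep="\t")
    frac_cols = [c for c in df.columns if c.startswith("frac_k")]
    out = []
    for (label, length, dna_nm), sub in df.groupby(
        ["dna_label", "dna_length", "dna_total_nM"], sort=False
    ):
        sub = sub.sort_values("protein_total_nM")
        out.append(
            EmsaTitration(
                dna_label=str(label),
                dna_length=int(length),
                dna_total=float(dna_nm) * 1e-9,
                protein_totals=sub["protein_total_nM"].to_numpy() * 1e-9,
                fractions=sub[frac_cols].to_numpy(),
            )
        )
    return out


def write_titration_tsv(titrations: Sequence[EmsaTitration], path) -> None:
    frames = []
    for t in titrations:
        df = pd.DataFrame(
            t.fractions,
            columns=[f"frac_k{k}" for k in range(t.fractions.shape[1])],
        )
        df.insert(0, "protein_total_nM", t.protein_totals * 1e9)
        df.insert(0, "dna_total_nM", t.dna_total * 1e9)
        df.insert(0, "dna_length", t.dna_length)
        df.insert(0, "dna_label", t.dna_label)
        frames.append(df)
    pd.concat(frames).to_csv(path, sep="\t", index=False)
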