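"""Site-frequency-spectrum selection statistics.

This module computes the classic frequency-spectrum neutrality statistics
used to detect selection on a gene from population allele-count data:

* Watterson's :math:`\\theta_W`, pairwise diversity :math:`\\theta_\\pi`,
  the high-frequency-weighted :math:`\\theta_H` and :math:`\\theta_L`;
* Tajima's ``D`` together with its theoretical minimum ``D_min`` for the
  observed number of segregating sites, so that ``D/D_min`` can be compared
  across genes with very different SNP counts;
* Fay and Wu's ``H`` (raw and variance-normalized) and Zeng's ``E``;
* the joint ``DH`` test, calibrated against a neutral coalescent null
  conditioned on the observed number of segregating sites ``S``.

All statistics operate on an *unfolded* site frequency spectrum: the counts
``xi[i]`` of segregating sites at which exactly ``i`` of ``n`` sampled
chromosomes carry the derived allele, ``i = 1..n-1``.

Sites genotyped in different numbers of chromosomes are harmonized by
hypergeometric projection down to a common sample size before any statistic
is computed (see :func:`build_sfs`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "FrequencySpectrum",
    "TajimaConstants",
    "SelectionStatResult",
    "NeutralNullEnsemble",
    "DHTestResult",
    "sites_from_tsv",
    "sites_from_vcf",
    "filter_sites",
    "build_sfs",
    "tajima_constants",
    "theta_watterson",
    "theta_pi",
    "theta_h",
    "fay_wu_h",
    "theta_l",
    "tajimas_d",
    "tajimas_d_min",
    "normalized_h_and_e",
    "simulate_neutral_sfs",
    "dh_test",
    "dh_reject",
    "maf_ci_upper",
    "popscale_coefficient",
    "selection_scan",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrequencySpectrum:
    """Unfolded site frequency spectrum for ``n`` sampled chromosomes.

    Parameters
    ----------
    n : int
        Haploid sample size (number of chromosomes), ``n >= 2``.
    xi : ndarray of shape (n - 1,)
        ``xi[i - 1]`` is the (possibly fractional, after projection) number
        of segregating sites with derived-allele count ``i``.
    folded : bool
        True if derived/ancestral polarity is unknown.  The statistics that
        up-weight high-frequency derived alleles (theta_H, theta_L, H, E)
        are undefined on folded spectra and refuse to compute.
    """

    n: int
    xi: np.ndarray
    folded: bool = False

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"sample size n must be >= 2, got {self.n}")
        xi = np.asarray(self.xi, dtype=float)
        if xi.shape != (self.n - 1,):
            raise ValueError(
                f"xi must have length n - 1 = {self.n - 1}, got {xi.shape}"
            )
        if np.any(xi < 0) or not np.all(np.isfinite(xi)):
            raise ValueError("xi entries must be finite and non-negative")
        object.__setattr__(self, "xi", xi)

    @property
    def S(self) -> float:
        """Total number of segregating sites (sum of all classes)."""
        return float(self.xi.sum())

    @property
    def i(self) -> np.ndarray:
        """Derived-allele counts 1..n-1 matching ``xi``."""
        return np.arange(1, self.n)

    @classmethod
    def from_counts(cls, n: int, counts: dict[int, float], folded: bool = False
                    ) -> "FrequencySpectrum":
        """Build a spectrum from a sparse ``{derived_count: n_sites}`` dict."""
        xi = np.zeros(n - 1)
        for i, c in counts.items():
            if not 1 <= i <= n - 1:
                raise ValueError(f"class {i} outside 1..{n - 1}")
            xi[i - 1] = c
        return cls(n=n, xi=xi, folded=folded)


@dataclass(frozen=True)
class TajimaConstants:
    """Variance coefficients for Tajima's D at sample size ``n``."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


@dataclass
class SelectionStatResult:
    """Per-region bundle of frequency-spectrum selection statistics."""

    n: int
    n_sites_used: int
    S: float
    theta_w: float
    theta_pi: float
    theta_h: float
    theta_l: float
    D: float | None
    D_min: float | None
    D_norm: float | None
    H_raw: float
    H_norm: float | None
    E: float | None
    p_D: float | None = None
    p_H: float | None = None
    p_DH: float | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class NeutralNullEnsemble:
    """Replicate D / H / E statistics under the standard neutral coalescent,
    every replicate conditioned on exactly ``S`` segregating sites."""

    n: int
    S: int
    D: np.ndarray
    H_raw: np.ndarray
    H_norm: np.ndarray
    E: np.ndarray
    n_reps: int
    seed: int


@dataclass
class DHTestResult:
    """Empirical tail probabilities against a conditioned neutral null.

    ``p_D`` and ``p_H`` are marginal lower-tail probabilities (the sweep
    signature is jointly negative D and H).  ``p_DH`` is the joint
    lower-orthant fraction.  ``p_joint`` is the calibrated joint p-value
    from the max-marginal-rank statistic; rejecting when
    ``p_joint <= alpha`` gives a test whose null rejection rate is alpha.
    All use add-one smoothing so no p-value is exactly zero.
    """

    p_D: float
    p_H: float
    p_DH: float
    p_joint: float
    D_obs: float
    H_obs: float
    n_reps: int


# ---------------------------------------------------------------------------
# Site tables
# ---------------------------------------------------------------------------

SITE_COLUMNS = ["position", "derived_count", "total_count"]


def _with_maf(sites: pd.DataFrame) -> pd.DataFrame:
    sites = sites.copy()
    d = sites["derived_count"].to_numpy(dtype=float)
    t = sites["total_count"].to_numpy(dtype=float)
    if np.any(d < 0) or np.any(d > t):
        raise ValueError("require 0 <= derived_count <= total_count")
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.minimum(d, t - d) / t
    sites["maf"] = np.where(t > 0, maf, np.nan)
    return sites


def sites_from_tsv(path) -> pd.DataFrame:
    """Read a per-site allele-count table.

    Expects columns ``position``, ``derived_count`` (or ``minor_count``) and
    ``total_count``; adds a ``maf`` column.
    """
    df = pd.read_csv(path, sep="\t")
    if "derived_count" not in df.columns and "minor_count" in df.columns:
        df = df.rename(columns={"minor_count": "derived_count"})
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"site table missing columns: {missing}")
    return _with_maf(df[SITE_COLUMNS])


def sites_from_vcf(path) -> pd.DataFrame:
    """Ingest per-site counts from VCF ``INFO`` AC/AN fields.

    The ALT allele count is taken as the derived count; multi-allelic
    records use the first ALT.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                continue
            info = dict(
                kv.split("=", 1) if "=" in kv else (kv, "")
                for kv in parts[7].split(";")
            )
            if "AC" not in info or "AN" not in info:
                continue
            ac = int(info["AC"].split(",")[0])
            an = int(info["AN"])
            rows.append({"position": int(parts[1]),
                         "derived_count": ac, "total_count": an})
    if not rows:
        return _with_maf(pd.DataFrame(columns=SITE_COLUMNS))
    return _with_maf(pd.DataFrame(rows))


def filter_sites(sites: pd.DataFrame, min_total: int = 200) -> pd.DataFrame:
    """Drop sites genotyped in fewer than ``min_total`` chromosomes.

    Low-coverage dbSNP/ExAC sites carry unreliable frequencies; the default
    cutoff keeps ``total_count >= 200`` (inclusive).
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    if len(sites) == 0:
        return sites.copy()
    return sites[sites["total_count"] >= min_total].copy()


def build_sfs(sites: pd.DataFrame, n_project: int) -> FrequencySpectrum:
    """Project heterogeneous-coverage sites to a common sample size.

    Each site genotyped in ``total_count`` chromosomes with ``derived_count``
    derived alleles contributes its expected class occupancy under
    hypergeometric downsampling to ``n_project`` chromosomes.  Mass that
    projects to monomorphic classes (0 or ``n_project`` derived copies) is
    discarded, so the spectrum sums to at most the number of input sites.
    """
    if n_project < 4:
        raise ValueError("n_project must be >= 4")
    tot = sites["total_count"].to_numpy(dtype=int)
    der = sites["derived_count"].to_numpy(dtype=int)
    if np.any(tot < n_project):
        bad = int((tot < n_project).sum())
        raise ValueError(
            f"{bad} site(s) have total_count < n_project={n_project}; "
            "filter them out or lower n_project"
        )
    xi = np.zeros(n_project - 1)
    j = np.arange(1, n_project)
    for t, d in zip(tot, der):
        if d == 0 or d == t:
            continue  # monomorphic site contributes nothing
        xi += hypergeom.pmf(j, t, d, n_project)
    return FrequencySpectrum(n=n_project, xi=xi)


def default_projection_n(sites: pd.DataFrame, pct: float = 5.0) -> int:
    """Default common sample size: the 5th percentile of total_count."""
    return int(np.percentile(sites["total_count"], pct))


# ---------------------------------------------------------------------------
# Theta estimators
# ---------------------------------------------------------------------------


def tajima_constants(n: int) -> TajimaConstants:
    """Tajima's variance coefficients a1..e2 for sample size ``n``."""
    if n < 2:
        raise ValueError("n must be >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n=n, a1=a1, a2=a2, b1=b1, b2=b2,
                           c1=c1, c2=c2, e1=e1, e2=e2)


def theta_watterson(sfs: FrequencySpectrum) -> float:
    """Watterson's estimator S / a1."""
    return sfs.S / tajima_constants(sfs.n).a1


def theta_pi(sfs: FrequencySpectrum) -> float:
    """Pairwise nucleotide diversity, sum_i 2 i (n-i) xi_i / (n (n-1))."""
    n, i = sfs.n, sfs.i
    return float(np.sum(2.0 * i * (n - i) * sfs.xi) / (n * (n - 1)))


def _require_unfolded(sfs: FrequencySpectrum, what: str) -> None:
    if sfs.folded:
        raise ValueError(f"{what} is undefined on a folded spectrum "
                         "(derived-allele polarity required)")


def theta_h(sfs: FrequencySpectrum) -> float:
    """Fay and Wu's high-frequency-weighted estimator,
    sum_i 2 i^2 xi_i / (n (n-1))."""
    _require_unfolded(sfs, "theta_H")
    n, i = sfs.n, sfs.i
    return float(np.sum(2.0 * i**2 * sfs.xi) / (n * (n - 1)))


def fay_wu_h(sfs: FrequencySpectrum) -> float:
    """Fay and Wu's H = theta_pi - theta_H (negative after a sweep)."""
    return theta_pi(sfs) - theta_h(sfs)


def theta_l(sfs: FrequencySpectrum) -> float:
    """Zeng's theta_L = sum_i i xi_i / (n - 1).

    Satisfies the identity theta_pi + theta_H = 2 theta_L exactly.
    """
    _require_unfolded(sfs, "theta_L")
    return float(np.sum(sfs.i * sfs.xi) / (sfs.n - 1))


# ---------------------------------------------------------------------------
# Tajima's D and its theoretical minimum
# ---------------------------------------------------------------------------


def _d_denominator(n: int, S: float) -> float:
    c = tajima_constants(n)
    return float(np.sqrt(c.e1 * S + c.e2 * S * (S - 1)))


def tajimas_d(sfs: FrequencySpectrum) -> float:
    """Tajima's D = (theta_pi - theta_W) / sqrt(e1 S + e2 S (S-1)).

    Requires ``n >= 4`` and ``S >= 2`` for the variance to be defined.
    """
    if sfs.n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    S = sfs.S
    if S < 2:
        raise ValueError(f"Tajima's D is undefined for S = {S} (< 2)")
    return (theta_pi(sfs) - theta_watterson(sfs)) / _d_denominator(sfs.n, S)


def tajimas_d_min(sfs: FrequencySpectrum) -> float:
    """Theoretical minimum of D for the observed (n, S).

    The minimizing configuration places every segregating site as a
    singleton, giving theta_pi = 2 S / n.  ``D / D_min`` is the normalized
    D used to compare genes with different SNP counts.
    """
    if sfs.n < 4:
        raise ValueError("D_min requires n >= 4")
    S = sfs.S
    if S < 2:
        raise ValueError(f"D_min is undefined for S = {S} (< 2)")
    c = tajima_constants(sfs.n)
    return (2.0 * S / sfs.n - S / c.a1) / _d_denominator(sfs.n, S)


def normalized_d(sfs: FrequencySpectrum) -> float | None:
    """D / D_min, or None when undefined (S < 2 or D_min >= 0)."""
    if sfs.S < 2:
        return None
    dmin = tajimas_d_min(sfs)
    if dmin >= 0:
        return None
    return tajimas_d(sfs) / dmin


# ---------------------------------------------------------------------------
# Normalized H and E (Zeng, Fu, Shi & Wu 2006)
# ---------------------------------------------------------------------------


def _theta_moments(n: int, S: float) -> tuple[float, float]:
    """Unbiased estimators of theta and theta^2 from S."""
    c = tajima_constants(n)
    theta = S / c.a1
    theta2 = S * (S - 1) / (c.a1**2 + c.a2)
    return theta, theta2


def _var_pi_minus_l(n: int, S: float) -> float:
    c = tajima_constants(n)
    bn = c.a2
    bn1 = bn + 1.0 / n**2  # sum_{i=1}^{n} 1/i^2
    theta, theta2 = _theta_moments(n, S)
    lin = (n - 2) / (6.0 * (n - 1))
    quad = (18.0 * n**2 * (3 * n + 2) * bn1
            - (88.0 * n**3 + 9 * n**2 - 13 * n + 6)) / (9.0 * n * (n - 1) ** 2)
    return lin * theta + quad * theta2


def _var_l_minus_w(n: int, S: float) -> float:
    c = tajima_constants(n)
    an, bn = c.a1, c.a2
    theta, theta2 = _theta_moments(n, S)
    lin = n / (2.0 * (n - 1)) - 1.0 / an
    quad = (bn / an**2
            + 2.0 * (n / (n - 1.0)) ** 2 * bn
            - 2.0 * (n * bn - n + 1) / ((n - 1.0) * an)
            - (3.0 * n + 1) / (n - 1.0))
    return lin * theta + quad * theta2


def normalized_h_and_e(sfs: FrequencySpectrum) -> tuple[float, float]:
    """Variance-normalized H and the E statistic.

    ``H_norm = (theta_pi - theta_L) / sqrt(Var)`` detects an excess of
    high-frequency derived alleles; ``E = (theta_L - theta_W) / sqrt(Var)``
    contrasts high-frequency and low-frequency classes.  Variances follow
    the published second-order formulas with theta and theta^2 estimated
    from S.
    """
    if sfs.n < 4:
        raise ValueError("normalized H and E require n >= 4")
    _require_unfolded(sfs, "normalized H/E")
    S = sfs.S
    if S < 2:
        raise ValueError(f"normalized H and E undefined for S = {S} (< 2)")
    tp = theta_pi(sfs)
    tl = theta_l(sfs)
    tw = theta_watterson(sfs)
    h_norm = (tp - tl) / np.sqrt(_var_pi_minus_l(sfs.n, S))
    e = (tl - tw) / np.sqrt(_var_l_minus_w(sfs.n, S))
    return float(h_norm), float(e)


# ---------------------------------------------------------------------------
# Neutral coalescent null conditioned on S
# ---------------------------------------------------------------------------


def _coalescent_class_lengths(n: int, rng: np.random.Generator) -> np.ndarray:
    """Total branch length subtending i = 1..n-1 leaves, one Kingman tree.

    Runs the standard coalescent backwards: with k active lineages the
    waiting time is Exp(k(k-1)/2) (units of 2N generations) and a uniformly
    random pair merges.  Each active lineage contributes the epoch length to
    the class equal to the number of leaves it subtends.
    """
    counts = np.ones(n, dtype=np.int64)
    lengths = np.zeros(n, dtype=float)  # index = leaves subtended
    k = n
    while k > 1:
        t = rng.exponential(2.0 / (k * (k - 1)))
        np.add.at(lengths, counts[:k], t)
        i, j = rng.choice(k, size=2, replace=False)
        counts[min(i, j)] += counts[max(i, j)]
        counts[max(i, j)] = counts[k - 1]
        k -= 1
    return lengths[1:n]


def simulate_neutral_sfs(n: int, S: int, n_reps: int, seed: int
                         ) -> NeutralNullEnsemble:
    """Neutral null ensemble with exactly ``S`` mutations per replicate.

    Per replicate a Kingman genealogy is drawn for ``n`` tips and ``S``
    mutations are placed multinomially with probabilities proportional to
    the branch length subtending each frequency class.  Conditioning on S
    removes the nuisance dependence on theta, matching how the joint DH
    test is applied to per-gene SNP counts.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    if S < 1 or n_reps < 1:
        raise ValueError("S and n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    i = np.arange(1, n)
    c = tajima_constants(n)
    w_pi = 2.0 * i * (n - i) / (n * (n - 1))
    w_h = 2.0 * i**2 / (n * (n - 1))
    w_l = i / (n - 1.0)
    denom_d = _d_denominator(n, S)
    sd_h = np.sqrt(_var_pi_minus_l(n, S))
    sd_e = np.sqrt(_var_l_minus_w(n, S))

    D = np.empty(n_reps)
    H_raw = np.empty(n_reps)
    H_norm = np.empty(n_reps)
    E = np.empty(n_reps)
    tw = S / c.a1
    for r in range(n_reps):
        L = _coalescent_class_lengths(n, rng)
        xi = rng.multinomial(S, L / L.sum())
        tp = float(w_pi @ xi)
        th = float(w_h @ xi)
        tl = float(w_l @ xi)
        D[r] = (tp - tw) / denom_d
        H_raw[r] = tp - th
        H_norm[r] = (tp - tl) / sd_h
        E[r] = (tl - tw) / sd_e
    return NeutralNullEnsemble(n=n, S=S, D=D, H_raw=H_raw, H_norm=H_norm,
                               E=E, n_reps=n_reps, seed=seed)


def _smoothed_tail(reps: np.ndarray, obs: float, lower: bool) -> float:
    hits = (reps <= obs) if lower else (reps >= obs)
    return (1 + int(hits.sum())) / (len(reps) + 1)


def dh_test(sfs: FrequencySpectrum, null: NeutralNullEnsemble,
            lower: bool = True) -> DHTestResult:
    """Empirical significance of D and H against a conditioned null.

    ``lower=True`` (default) tests the sweep direction: small D and small
    H.  ``p_DH`` is the joint lower-orthant fraction; ``p_joint`` is the
    calibrated joint p-value obtained by ranking the larger of the two
    marginal CDF values, which rejects both statistics jointly at an exact
    nominal level.
    """
    if null.n != sfs.n or abs(null.S - sfs.S) > 1e-9:
        raise ValueError(
            f"null ensemble (n={null.n}, S={null.S}) does not match the "
            f"observed spectrum (n={sfs.n}, S={sfs.S})"
        )
    d_obs = tajimas_d(sfs)
    h_obs = fay_wu_h(sfs)
    p_d = _smoothed_tail(null.D, d_obs, lower)
    p_h = _smoothed_tail(null.H_raw, h_obs, lower)
    if lower:
        joint_hits = (null.D <= d_obs) & (null.H_raw <= h_obs)
    else:
        joint_hits = (null.D >= d_obs) & (null.H_raw >= h_obs)
    p_dh = (1 + int(joint_hits.sum())) / (null.n_reps + 1)

    # Calibrated joint statistic: the larger of the two marginal empirical
    # CDF values; small values mean both statistics are jointly extreme.
    sign = 1.0 if lower else -1.0
    fd_rep = _ecdf_values(sign * null.D)
    fh_rep = _ecdf_values(sign * null.H_raw)
    m_rep = np.maximum(fd_rep, fh_rep)
    fd_obs = np.mean(sign * null.D <= sign * d_obs)
    fh_obs = np.mean(sign * null.H_raw <= sign * h_obs)
    m_obs = max(fd_obs, fh_obs)
    p_joint = (1 + int(np.sum(m_rep <= m_obs))) / (null.n_reps + 1)
    return DHTestResult(p_D=p_d, p_H=p_h, p_DH=p_dh, p_joint=p_joint,
                        D_obs=d_obs, H_obs=h_obs, n_reps=null.n_reps)


def _ecdf_values(x: np.ndarray) -> np.ndarray:
    """Fraction of the sample <= each element (ties share the upper rank)."""
    order = np.argsort(x, kind="mergesort")
    sorted_x = x[order]
    upper = np.searchsorted(sorted_x, x, side="right")
    return upper / len(x)


def dh_reject(sfs: FrequencySpectrum, null: NeutralNullEnsemble,
              alpha: float = 0.05, lower: bool = True) -> bool:
    """Joint DH rejection at nominal level ``alpha``.

    Rejects when both D and H fall below marginal critical values whose
    common marginal level is calibrated (via the max-rank statistic) so the
    joint null rejection rate equals alpha.
    """
    return dh_test(sfs, null, lower=lower).p_joint <= alpha


# ---------------------------------------------------------------------------
# MAF confidence profiling and scaled selection
# ---------------------------------------------------------------------------


def maf_ci_upper(mafs: Sequence[float], level: float = 0.95,
                 n_boot: int = 10_000, seed: int = 0) -> float:
    """Bootstrap percentile upper bound of the mean minor-allele frequency.

    A gene under strong purifying selection shows a mean MAF whose CI upper
    bound sits far below genome background.  The upper bound of the
    two-sided ``level`` interval is the ``1 - (1 - level)/2`` percentile of
    the bootstrap distribution of the mean.
    """
    mafs = np.asarray(mafs, dtype=float)
    if mafs.size == 0:
        raise ValueError("maf_ci_upper requires at least one value")
    if np.any((mafs < 0) | (mafs > 0.5)):
        raise ValueError("MAF values must lie in [0, 0.5]")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, mafs.size, size=(n_boot, mafs.size))
    means = mafs[idx].mean(axis=1)
    return float(np.quantile(means, 1.0 - (1.0 - level) / 2.0))


def popscale_coefficient(s: float, ne: float) -> float:
    """Population-scaled selection coefficient S = 2 Ne s."""
    if ne <= 0:
        raise ValueError("effective population size must be positive")
    return 2.0 * ne * s


# ---------------------------------------------------------------------------
# One-call region scan
# ---------------------------------------------------------------------------


def selection_scan(sites: pd.DataFrame, min_total: int = 200,
                   n_project: int | None = None,
                   null_reps: int = 0, seed: int = 0) -> SelectionStatResult:
    """Filter, project and compute every selection statistic for one region.

    With ``null_reps > 0`` a conditioned neutral ensemble is simulated and
    the empirical DH tail probabilities are attached.
    """
    kept = filter_sites(sites, min_total)
    if len(kept) == 0:
        raise ValueError("no sites left after coverage filtering")
    if n_project is None:
        n_project = default_projection_n(kept)
    sfs = build_sfs(kept, n_project)
    S = sfs.S
    res = SelectionStatResult(
        n=sfs.n, n_sites_used=len(kept), S=S,
        theta_w=theta_watterson(sfs), theta_pi=theta_pi(sfs),
        theta_h=theta_h(sfs), theta_l=theta_l(sfs),
        D=None, D_min=None, D_norm=None,
        H_raw=fay_wu_h(sfs), H_norm=None, E=None,
    )
    if S >= 2:
        res.D = tajimas_d(sfs)
        res.D_min = tajimas_d_min(sfs)
        res.D_norm = normalized_d(sfs)
        res.H_norm, res.E = normalized_h_and_e(sfs)
    if null_reps > 0 and S >= 2:
        null = simulate_neutral_sfs(sfs.n, int(round(S)), null_reps, seed)
        # mutation placement is integer-valued; round projected S for the null
        sfs_int = FrequencySpectrum(
            sfs.n, sfs.xi * (round(S) / S) if S else sfs.xi)
        dh = dh_test(sfs_int, null)
        res.p_D, res.p_H, res.p_DH = dh.p_D, dh.p_H, dh.p_DH
    return res


def result_to_json(res: SelectionStatResult, seed: int | None = None,
                   **params) -> str:
    payload = res.to_dict()
    if seed is not None:
        payload["seed"] = seed
    payload.update(params)
    return json.dumps(payload, indent=2)
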