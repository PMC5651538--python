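"""Permutation scoring of anti-aging indications.

A compound with targets enriched in aging-associated proteins (AAPs) is a
candidate for anti-aging indications. Under the null hypothesis the
compound's n targets fall on AAPs no more often than random genes would:
each permutation redraws the AAP label set — K genes sampled uniformly
without replacement from the N-gene protein-coding universe — and records
the overlap S with the compound's fixed target set. The nominal P is the
fraction of permutations whose overlap reaches the observed count x, and

    Z = (x - mu) / sigma

with mu and sigma the mean and standard deviation of the permuted
overlaps. Because the permutation draw is a uniform K-subset, the null
overlap is exactly hypergeometric(N, K, n); closed-form moments and tail
probabilities serve as an independent oracle for the Monte-Carlo
estimates. P-values across a compound cohort are Benjamini-Hochberg
adjusted to q-values.

The module is organized statsmodels-style: :class:`IndicationModel` binds
target profiles, the AAP set and a :class:`PermutationConfig`; ``fit()``
returns :class:`IndicationResults` with the per-drug table, significance
counts and a text ``summary()``. :func:`prioritize_indications` is the
functional entry point over the same machinery.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import DEFAULT_UNIVERSE_SIZE

DEFAULT_N_PERMUTATIONS = 100_000


@dataclass(frozen=True)
class PermutationConfig:
    """Null-model configuration for indication scoring.

    ``aap_size`` (K) defaults to the size of the supplied AAP set;
    ``universe_size`` (N) defaults to the NCBI protein-coding count.
    ``tail_mode`` 'at_least' counts permutations with overlap >= x (the
    standard permutation convention); 'strict_greater' counts > x.
    ``pseudocount`` adds 1 to numerator and denominator so reported P is
    never exactly zero.
    """

    universe_size: int = DEFAULT_UNIVERSE_SIZE
    aap_size: int | None = None
    n_permutations: int = DEFAULT_N_PERMUTATIONS
    seed: int = 0
    tail_mode: str = "at_least"
    pseudocount: bool = False

    def __post_init__(self) -> None:
        if self.aap_size is not None and self.aap_size > self.universe_size:
            raise ValueError("aap_size K cannot exceed universe_size N")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.tail_mode not in ("at_least", "strict_greater"):
            raise ValueError("tail_mode must be 'at_least' or 'strict_greater'")


@dataclass(frozen=True)
class PermutationNull:
    """Monte-Carlo null for one target-set size: samples and moments."""

    samples: np.ndarray
    mean: float
    std: float


def observed_aap_count(targets: Iterable[str], aap_set: Iterable[str]) -> int:
    """x — the number of a compound's targets that are AAPs."""
    return len(set(targets) & set(aap_set))


def _substream(seed: int, drug_id: str) -> np.random.Generator:
    """Per-drug RNG substream independent of drug iteration order."""
    digest = hashlib.sha256(str(drug_id).encode("utf-8")).digest()
    key = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def permutation_null(
    n_targets: int,
    config: PermutationConfig,
    rng: np.random.Generator | None = None,
) -> PermutationNull:
    """Simulate the permutation null for a fixed target-set size.

    Each permutation draws K genes uniformly without replacement from the
    N-gene universe and records the overlap with the drug's n fixed
    targets. The draw is realized exactly by the sequential conditional
    scheme: scanning the n targets, target t is in the K-subset with
    probability (K - j) / (N - t) given that j of the first t targets are
    (vectorized over permutations), which is the distribution of the
    literal K-subset draw restricted to the target positions.

    The standard deviation uses the sample (m - 1) denominator.
    """
    N = config.universe_size
    K = config.aap_size
    if K is None:
        raise ValueError("config.aap_size must be resolved before simulation")
    if n_targets > N:
        raise ValueError(f"n_targets={n_targets} exceeds universe size {N}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = config.n_permutations
    overlaps = np.zeros(m, dtype=np.int64)
    for t in range(n_targets):
        p = (K - overlaps) / (N - t)
        overlaps += rng.random(m) < p
    mean = float(overlaps.mean())
    std = float(overlaps.std(ddof=1)) if m > 1 else 0.0
    return PermutationNull(overlaps, mean, std)


def hypergeom_moments(
    n: int, K: int, N: int
) -> tuple[float, float, Callable[[int], float]]:
    """Closed-form null moments and upper tail for the overlap statistic.

    mu = nK/N; sigma^2 = n (K/N)(1 - K/N)(N - n)/(N - 1);
    tail(x) = P(X >= x) for X ~ hypergeometric(N, K, n).
    """
    if not (0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"invalid sizes n={n}, K={K}, N={N}")
    mu = n * K / N
    if N <= 1:
        sigma = 0.0
    else:
        sigma = math.sqrt(n * (K / N) * (1 - K / N) * (N - n) / (N - 1))
    rv = stats.hypergeom(N, K, n)

    def tail(x: int) -> float:
        if x <= 0:
            return 1.0
        return float(rv.sf(x - 1))

    return mu, sigma, tail


def permutation_pvalue(
    x: int,
    samples: np.ndarray,
    mode: str = "at_least",
    pseudocount: bool = False,
) -> float:
    """Nominal P from permuted overlap samples.

    'at_least' counts samples >= x (default); 'strict_greater' counts > x.
    With ``pseudocount`` the estimate is (hits + 1) / (m + 1).
    """
    if x < 0:
        raise ValueError("x must be non-negative")
    samples = np.asarray(samples)
    if samples.size == 0:
        raise ValueError("no permutation samples")
    if mode == "at_least":
        hits = int(np.count_nonzero(samples >= x))
    elif mode == "strict_greater":
        hits = int(np.count_nonzero(samples > x))
    else:
        raise ValueError("mode must be 'at_least' or 'strict_greater'")
    if pseudocount:
        return (hits + 1) / (samples.size + 1)
    return hits / samples.size


def z_score(x: float, mu: float, sigma: float) -> float:
    """Z = (x - mu) / sigma; NaN (undefined) when sigma = 0."""
    if sigma == 0 or not math.isfinite(sigma):
        return float("nan")
    return (x - mu) / sigma


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class IndicationModel:
    """Permutation model for anti-aging indication scoring of a drug cohort.

    Parameters
    ----------
    profiles : mapping of drug id -> iterable of target gene symbols
    aap_set : the aging-associated protein gene set
    config : PermutationConfig; ``aap_size`` resolves to ``len(aap_set)``
        when unset.
    """

    def __init__(
        self,
        profiles: Mapping[str, Iterable[str]],
        aap_set: Iterable[str],
        config: PermutationConfig = PermutationConfig(),
    ) -> None:
        if not profiles:
            raise ValueError("no target profiles supplied")
        self.profiles = {str(d): frozenset(ts) for d, ts in profiles.items()}
        self.aap_set = frozenset(aap_set)
        if config.aap_size is None:
            config = replace(config, aap_size=len(self.aap_set))
        self.config = config

    @classmethod
    def from_network(cls, net, aap_set, config=PermutationConfig()):
        """Build drug -> target-gene profiles from an annotated DTINetwork."""
        profiles = {}
        for drug in net.drugs:
            genes = {
                g
                for t in net.drug_targets(drug)
                if (g := net.target_gene(t)) is not None
            }
            profiles[drug] = genes
        return cls(profiles, aap_set, config)

    def fit(self) -> "IndicationResults":
        cfg = self.config
        rows = []
        for drug in sorted(self.profiles):
            targets = self.profiles[drug]
            n = len(targets)
            x = observed_aap_count(targets, self.aap_set)
            if n == 0:
                rows.append((drug, 0, 0, 0.0, 0.0, float("nan"), 1.0, True))
                continue
            rng = _substream(cfg.seed, drug)
            null = permutation_null(n, cfg, rng=rng)
            p = permutation_pvalue(
                x, null.samples, cfg.tail_mode, cfg.pseudocount
            )
            rows.append(
                (drug, n, x, null.mean, null.std, z_score(x, null.mean, null.std), p, False)
            )
        frame = pd.DataFrame(
            rows,
            columns=["drug", "n_targets", "x", "mu", "sigma", "z", "p", "empty_profile"],
        )
        frame["q"] = bh_adjust(frame["p"].to_numpy())
        # rank: ascending q, then descending Z (NaN last), then drug id
        frame = frame.sort_values(
            ["q", "z", "drug"],
            ascending=[True, False, True],
            na_position="last",
            ignore_index=True,
        )
        frame = frame[
            ["drug", "n_targets", "x", "mu", "sigma", "z", "p", "q", "empty_profile"]
        ]
        return IndicationResults(frame, self.config)


@dataclass
class IndicationResults:
    """Ranked indication table with significance counts and a summary."""

    frame: pd.DataFrame
    config: PermutationConfig

    def n_significant(self, q_threshold: float = 0.05) -> int:
        return int((self.frame["q"] < q_threshold).sum())

    def significant_drugs(self, q_threshold: float = 0.05) -> list[str]:
        return self.frame.loc[self.frame["q"] < q_threshold, "drug"].tolist()

    def summary(self, top: int = 10) -> str:
        cfg = self.config
        lines = [
            "Anti-aging indication scoring (permutation null)",
            "=" * 52,
            f"drugs scored:        {len(self.frame)}",
            f"universe N:          {cfg.universe_size}",
            f"AAP draw size K:     {cfg.aap_size}",
            f"permutations:        {cfg.n_permutations} (seed {cfg.seed})",
            f"tail mode:           {cfg.tail_mode}",
            f"significant (q<0.05): {self.n_significant()}",
            "",
            self.frame.head(top).to_string(
                index=False,
                float_format=lambda v: f"{v:.4g}",
            ),
        ]
        return "\n".join(lines)


def prioritize_indications(
    profiles: Mapping[str, Iterable[str]],
    aap_set: Iterable[str],
    config: PermutationConfig = PermutationConfig(),
) -> IndicationResults:
    """Score every drug's target set against the AAP set; BH across all drugs.

    Returns :class:`IndicationResults`; the table has one row per drug with
    (n, x, mu, sigma, Z, P, q), ranked by ascending q then descending Z.
    Deterministic given ``config.seed`` and independent of input drug order
    (per-drug RNG substreams are keyed by drug id).
    """
    return IndicationModel(profiles, aap_set, config).fit()
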