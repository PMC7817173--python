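"""Pooled shRNA screen enrichment and gene-level hit calling.

The screen compares hairpin abundance between FACS-sorted basal
(alpha6-integrin high) and suprabasal (alpha6-integrin low) epidermal
compartments: hairpins enriched in the basal layer inhibit
differentiation (their knockdown traps cells in the progenitor
compartment), hairpins enriched suprabasally promote it.

The analysis normalises libraries with median-of-ratios size factors,
computes a per-hairpin basal/suprabasal log2 ratio and a p-value from
either a negative-binomial Wald test (method-of-moments dispersion) or
a paired sign-flip permutation test, applies Benjamini-Hochberg
correction across hairpins, and calls a gene a hit when at least two of
its hairpins are significantly enriched in the same direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientReplicatesError, InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneHit",
    "normalize_counts",
    "shrna_enrichment",
    "call_gene_hits",
]

_REQUIRED = ("gene", "shrna_id", "compartment", "replicate", "count")
PSEUDOCOUNT = 0.5


def _check_table(counts: pd.DataFrame) -> None:
    for col in _REQUIRED:
        if col not in counts.columns:
            raise InvalidInputError(f"count table missing column {col!r}")
    if (counts["count"] < 0).any():
        raise InvalidInputError("counts must be non-negative")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per library (compartment, replicate).

    The reference is the geometric mean of each hairpin across all
    libraries; hairpins with a zero anywhere are excluded from the
    reference, as in the standard RNA-seq normalisation.
    """
    _check_table(counts)
    mat = counts.pivot_table(
        index="shrna_id", columns=["compartment", "replicate"],
        values="count", aggfunc="sum",
    )
    if mat.isna().any().any():
        raise InvalidInputError("each shRNA must appear in every library")
    arr = mat.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise InvalidInputError("no shRNA has positive counts in all libraries")
    ref = np.exp(np.log(arr[positive]).mean(axis=1))
    sf = np.median(arr[positive] / ref[:, None], axis=0)
    if (sf <= 0).any():
        raise InvalidInputError("a library has an all-zero size factor")
    return pd.Series(sf, index=mat.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Append a ``norm_count`` column: count / library size factor."""
    sf = size_factors(counts)
    out = counts.copy()
    keys = list(zip(out["compartment"], out["replicate"]))
    out["norm_count"] = out["count"].to_numpy(dtype=float) / sf.loc[keys].to_numpy()
    return out


def _nb_wald(basal: np.ndarray, supra: np.ndarray, alpha: float) -> tuple[float, float]:
    """Wald z-test on the log2 ratio of NB means with dispersion alpha."""
    mb = basal.mean() + PSEUDOCOUNT
    ms = supra.mean() + PSEUDOCOUNT
    log2_ratio = np.log2(mb / ms)
    var_log = (1.0 / mb + alpha) / len(basal) + (1.0 / ms + alpha) / len(supra)
    se = np.sqrt(var_log) / np.log(2.0)
    z = log2_ratio / se
    return float(log2_ratio), float(2.0 * sps.norm.sf(abs(z)))


def _moment_dispersion(values: np.ndarray) -> float:
    """Method-of-moments NB dispersion: (s^2 - mu)/mu^2, floored at 0."""
    mu = values.mean()
    if mu <= 0:
        return 0.0
    s2 = values.var(ddof=1)
    return max(0.0, (s2 - mu) / mu**2)


def _permutation_p(log_ratios: np.ndarray, rng: np.random.Generator,
                   max_exact: int = 4096, n_sample: int = 2000) -> float:
    """Paired sign-flip permutation p for the mean per-replicate log-ratio."""
    n = len(log_ratios)
    obs = abs(log_ratios.mean())
    if 2**n <= max_exact:
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
    else:
        signs = rng.choice((1.0, -1.0), size=(n_sample, n))
    null = np.abs((signs * log_ratios).mean(axis=1))
    return float((1 + np.sum(null >= obs - 1e-12)) / (1 + len(null)))


def shrna_enrichment(
    counts: pd.DataFrame,
    method: str = "nb_wald",
    q_threshold: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-hairpin basal/suprabasal enrichment statistics.

    Accepts a raw or pre-normalised count table (``norm_count`` is
    computed if absent).  Returns one row per hairpin: ``log2_ratio``
    (basal over suprabasal, normalised, pseudocount 0.5), ``p_value``,
    BH ``q_value`` and ``direction`` in {basal, suprabasal, none} (none
    unless q <= q_threshold).

    ``nb_wald`` needs >=2 replicates per compartment; the hairpin
    dispersion is moderated by flooring each method-of-moments estimate
    at the across-hairpin median (few replicates make the raw estimate
    unstable).  ``permutation`` needs >=3 replicates for usable
    resolution and uses paired per-replicate log-ratios with sign
    flips.
    """
    if method not in ("nb_wald", "permutation"):
        raise InvalidInputError(f"unknown enrichment method {method!r}")
    df = counts if "norm_count" in counts.columns else normalize_counts(counts)
    wide = df.pivot_table(
        index=["gene", "shrna_id"], columns=["compartment", "replicate"],
        values="norm_count", aggfunc="sum",
    )
    basal_cols = [c for c in wide.columns if c[0] == "basal"]
    supra_cols = [c for c in wide.columns if c[0] == "suprabasal"]
    n_rep = min(len(basal_cols), len(supra_cols))
    if method == "nb_wald" and n_rep < 2:
        raise InsufficientReplicatesError("nb_wald needs >=2 replicates")
    if method == "permutation" and n_rep < 3:
        raise InsufficientReplicatesError("permutation needs >=3 replicates")

    basal = wide[basal_cols].to_numpy(dtype=float)
    supra = wide[supra_cols].to_numpy(dtype=float)

    if method == "nb_wald":
        disp = np.array(
            [
                0.5 * (_moment_dispersion(b) + _moment_dispersion(s))
                for b, s in zip(basal, supra)
            ]
        )
        disp_floor = float(np.median(disp))
        results = [
            _nb_wald(b, s, max(d, disp_floor))
            for b, s, d in zip(basal, supra, disp)
        ]
        log2_ratio = np.array([r[0] for r in results])
        p = np.array([r[1] for r in results])
    else:
        rng = np.random.default_rng(seed)
        # pair replicate i of basal with replicate i of suprabasal
        lr = np.log2((basal[:, :n_rep] + PSEUDOCOUNT) / (supra[:, :n_rep] + PSEUDOCOUNT))
        log2_ratio = lr.mean(axis=1)
        p = np.array([_permutation_p(row, rng) for row in lr])

    _, q, _, _ = multipletests(p, method="fdr_bh")
    direction = np.where(
        q <= q_threshold,
        np.where(log2_ratio > 0, "basal", np.where(log2_ratio < 0, "suprabasal", "none")),
        "none",
    )
    out = wide.index.to_frame(index=False)
    out["log2_ratio"] = log2_ratio
    out["p_value"] = p
    out["q_value"] = q
    out["direction"] = direction
    return out


@dataclass(frozen=True)
class GeneHit:
    gene: str
    call: str  # "basal_hit" | "suprabasal_hit" | "no_call"
    n_significant_consistent: int
    supporting_shrnas: tuple


def call_gene_hits(
    results: pd.DataFrame,
    min_consistent: int = 2,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Gene-level hit calls from per-hairpin enrichment results.

    A gene is a hit iff at least ``min_consistent`` of its hairpins pass
    the q threshold with the same direction; genes whose significant
    hairpins split across directions without either side reaching the
    minimum are not called.
    """
    if "gene" not in results.columns:
        raise InvalidInputError("results must carry a 'gene' column")
    rows = []
    for gene, g in results.groupby("gene", sort=True):
        sig = g[(g["q_value"] <= q_threshold) & (g["direction"] != "none")]
        n_basal = int((sig["direction"] == "basal").sum())
        n_supra = int((sig["direction"] == "suprabasal").sum())
        # "consistent" is strict: any significant hairpin in the opposite
        # direction voids the call
        if n_basal >= min_consistent and n_supra == 0:
            call, n_cons, support = (
                "basal_hit", n_basal,
                tuple(sig.loc[sig["direction"] == "basal", "shrna_id"]),
            )
        elif n_supra >= min_consistent and n_basal == 0:
            call, n_cons, support = (
                "suprabasal_hit", n_supra,
                tuple(sig.loc[sig["direction"] == "suprabasal", "shrna_id"]),
            )
        else:
            call, n_cons, support = "no_call", max(n_basal, n_supra), ()
        rows.append(
            {
                "gene": gene,
                "call": call,
                "n_significant_consistent": n_cons,
                "supporting_shrnas": ";".join(support),
            }
        )
    return pd.DataFrame(rows)
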