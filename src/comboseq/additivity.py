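"""Combination-treatment analysis: Venn partitions, concordance classes,
the expected-additive-effect statistic, observed-vs-expected regression,
and attenuation of one treatment's effect by the other.

The central quantity is the expected additive effect of a combined
treatment: the sum of the two single-treatment log2 fold-changes. Ordinary
least squares of the observed combined log2 fold-change on this sum, with
slope near 1 and high r-squared, indicates that the two treatments act
additively on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .de import DEGeneSet, bh_adjust
from .io import ValidationError

GeneSetLike = Union[DEGeneSet, frozenset, set]

VENN_REGIONS = (
    "A_only",
    "B_only",
    "AB_only",
    "A_B_not_AB",
    "A_AB_not_B",
    "B_AB_not_A",
    "A_B_AB",
)


def _genes(s: GeneSetLike) -> frozenset:
    return frozenset(s.genes) if isinstance(s, DEGeneSet) else frozenset(s)


def round_half_up_percent(numerator: int, denominator: int) -> int:
    """Integer percent with the round-half-up convention (54.5% -> 55%)."""
    if denominator <= 0:
        raise ValidationError("percent of an empty denominator is undefined")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


@dataclass(frozen=True)
class VennPartition:
    """The seven disjoint regions of three DE gene sets (A, B, combined)."""

    regions: Mapping

    def __post_init__(self):
        missing = set(VENN_REGIONS) - set(self.regions)
        if missing:
            raise ValidationError(f"missing Venn region(s): {sorted(missing)}")

    @property
    def commonAB(self) -> frozenset:
        """Genes DE under both single treatments (regardless of the combo)."""
        return self.regions["A_B_not_AB"] | self.regions["A_B_AB"]

    @property
    def union_singles(self) -> frozenset:
        """Genes DE under at least one single treatment."""
        return (
            self.regions["A_only"]
            | self.regions["B_only"]
            | self.regions["A_B_not_AB"]
            | self.regions["A_AB_not_B"]
            | self.regions["B_AB_not_A"]
            | self.regions["A_B_AB"]
        )

    @property
    def combo_overlap(self) -> frozenset:
        """Combination-DE genes that are also DE under a single treatment."""
        return self.regions["A_AB_not_B"] | self.regions["B_AB_not_A"] | self.regions["A_B_AB"]

    def counts(self) -> dict:
        """Region counts plus the derived marginals."""
        out = {k: len(v) for k, v in self.regions.items()}
        set_a = self.regions["A_only"] | self.regions["A_B_not_AB"] | self.regions["A_AB_not_B"] | self.regions["A_B_AB"]
        set_b = self.regions["B_only"] | self.regions["A_B_not_AB"] | self.regions["B_AB_not_A"] | self.regions["A_B_AB"]
        out["A_total"] = len(set_a)
        out["B_total"] = len(set_b)
        out["AB_total"] = len(self.regions["AB_only"] | self.combo_overlap)
        out["commonAB"] = len(self.commonAB)
        out["union_singles"] = len(self.union_singles)
        out["combo_overlap"] = len(self.combo_overlap)
        out["A_unshared"] = out["A_total"] - out["commonAB"]
        out["B_unshared"] = out["B_total"] - out["commonAB"]
        return out


def partition_sets(setA: GeneSetLike, setB: GeneSetLike, setAB: GeneSetLike) -> VennPartition:
    """Exact set algebra over the three DE gene sets."""
    A, B, AB = _genes(setA), _genes(setB), _genes(setAB)
    regions = {
        "A_only": A - B - AB,
        "B_only": B - A - AB,
        "AB_only": AB - A - B,
        "A_B_not_AB": (A & B) - AB,
        "A_AB_not_B": (A & AB) - B,
        "B_AB_not_A": (B & AB) - A,
        "A_B_AB": A & B & AB,
    }
    return VennPartition(regions)


@dataclass(frozen=True)
class ConcordanceClasses:
    """Sign-pair classification of genes DE under both single treatments."""

    both_up: frozenset
    both_down: frozenset
    A_up_B_down: frozenset
    A_down_B_up: frozenset

    @property
    def concordant(self) -> frozenset:
        return self.both_up | self.both_down

    @property
    def discordant(self) -> frozenset:
        return self.A_up_B_down | self.A_down_B_up

    @property
    def n(self) -> int:
        return len(self.concordant) + len(self.discordant)

    @property
    def concordant_percent(self) -> int:
        return round_half_up_percent(len(self.concordant), self.n)

    @property
    def discordant_percent(self) -> int:
        # defined as the complement so the pair always sums to 100
        return 100 - self.concordant_percent

    def counts(self) -> dict:
        return {
            "both_up": len(self.both_up),
            "both_down": len(self.both_down),
            "A_up_B_down": len(self.A_up_B_down),
            "A_down_B_up": len(self.A_down_B_up),
            "concordant": len(self.concordant),
            "discordant": len(self.discordant),
            "n": self.n,
            "concordant_percent": self.concordant_percent,
            "discordant_percent": self.discordant_percent,
        }


def classify_concordance(common, lfcA: Mapping, lfcB: Mapping) -> ConcordanceClasses:
    """Classify common DE genes by the signs of their two single-treatment lfc.

    An exactly zero log2 fold-change signals an upstream inconsistency (a DE
    gene with finite test output cannot have lfc 0) and raises.
    """
    common = _genes(common)
    classes = {"both_up": set(), "both_down": set(), "A_up_B_down": set(), "A_down_B_up": set()}
    for g in common:
        a, b = float(lfcA[g]), float(lfcB[g])
        if not (np.isfinite(a) and np.isfinite(b)):
            raise ValidationError(f"non-finite log2 fold-change for gene {g!r}")
        if a == 0.0 or b == 0.0:
            raise ValidationError(
                f"gene {g!r} has log2 fold-change exactly 0; a DE call with zero effect "
                "signals an upstream inconsistency"
            )
        if a > 0 and b > 0:
            classes["both_up"].add(g)
        elif a < 0 and b < 0:
            classes["both_down"].add(g)
        elif a > 0:
            classes["A_up_B_down"].add(g)
        else:
            classes["A_down_B_up"].add(g)
    return ConcordanceClasses(**{k: frozenset(v) for k, v in classes.items()})


def expected_additive_lfc(lfcA: float, lfcB: float) -> float:
    """The expected additive effect: the sum of the single-treatment log2 fc."""
    a, b = float(lfcA), float(lfcB)
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValidationError("expected additive effect requires finite inputs")
    return a + b


@dataclass(frozen=True)
class AdditivityFit:
    """Simple linear regression of observed combined lfc on the additive sum."""

    subset_name: str
    n: int
    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    slope_pvalue: float

    def summary(self) -> str:
        return (
            f"additivity fit [{self.subset_name}]: n={self.n}, "
            f"slope={self.slope:.4f}, intercept={self.intercept:.4f}, "
            f"r={self.pearson_r:.4f}, r^2={self.r_squared:.4f}, "
            f"slope p={self.slope_pvalue:.3g}"
        )

    def to_dict(self) -> dict:
        return {
            "subset_name": self.subset_name,
            "n": self.n,
            "slope": self.slope,
            "intercept": self.intercept,
            "pearson_r": self.pearson_r,
            "r_squared": self.r_squared,
            "slope_pvalue": self.slope_pvalue,
        }


def fit_additivity(observed, expected, subset, subset_name: str) -> AdditivityFit:
    """OLS of observed combined log2 fc on the expected additive effect.

    ``observed`` and ``expected`` are gene-indexed mappings/Series; the fit
    runs on ``subset`` (at least 3 genes with finite values on both sides).
    """
    genes = sorted(_genes(subset))
    if len(genes) < 3:
        raise ValidationError(f"additivity fit needs >= 3 genes, got {len(genes)}")
    obs = np.array([float(observed[g]) for g in genes])
    exp_ = np.array([float(expected[g]) for g in genes])
    if not (np.all(np.isfinite(obs)) and np.all(np.isfinite(exp_))):
        raise ValidationError("additivity fit requires finite observed and expected values")
    if np.ptp(exp_) == 0.0:
        raise ValidationError("expected additive effect has zero variance; slope undefined")
    fit = linregress(exp_, obs)
    return AdditivityFit(
        subset_name=subset_name,
        n=len(genes),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        r_squared=float(fit.rvalue) ** 2,
        slope_pvalue=float(fit.pvalue),
    )


def standard_additivity_fits(
    result_A: pd.DataFrame,
    result_B: pd.DataFrame,
    result_AB: pd.DataFrame,
    setA: GeneSetLike,
    setB: GeneSetLike,
    setAB: GeneSetLike,
) -> dict:
    """The three standard observed-vs-expected fits.

    Subsets: the union of single-treatment DE genes, their intersection
    (common targets), and the combination-only genes. The combination-only
    fit deliberately uses single-treatment fold-change estimates for genes
    that are not DE in the single treatments — the estimates exist
    regardless of significance.
    """
    lfcA = result_A.set_index("gene_id")["log2fc"]
    lfcB = result_B.set_index("gene_id")["log2fc"]
    observed = result_AB.set_index("gene_id")["log2fc"]
    expected = lfcA + lfcB
    A, B, AB = _genes(setA), _genes(setB), _genes(setAB)
    subsets = {
        "union_singles": A | B,
        "common": A & B,
        "combo_only": AB - (A | B),
    }
    fits = {}
    for name, subset in subsets.items():
        if len(subset) >= 3:
            fits[name] = fit_additivity(observed, expected, subset, name)
    return fits


@dataclass(frozen=True)
class AttenuationResult:
    """Genes whose combined-treatment response significantly opposes the
    single-treatment-B response."""

    candidate_set: frozenset
    attenuated: frozenset
    fraction: Optional[float]
    n_excluded_missing: int = 0

    def counts(self) -> dict:
        return {
            "n_candidates": len(self.candidate_set),
            "n_attenuated": len(self.attenuated),
            "fraction": self.fraction,
            "percent": (
                round_half_up_percent(len(self.attenuated), len(self.candidate_set))
                if self.candidate_set
                else None
            ),
            "n_excluded_missing": self.n_excluded_missing,
        }


def attenuation(
    setB: GeneSetLike,
    result_B: pd.DataFrame,
    result_AB_vs_B: pd.DataFrame,
    alpha: float = 0.05,
) -> AttenuationResult:
    """Quantify attenuation of treatment B's effect by co-treatment with A.

    A candidate gene (DE for B vs vehicle) is attenuated when the
    combo-vs-B contrast is significant (BH within the candidate set,
    ``padj < alpha``) with sign opposite to its B-vs-vehicle effect. Genes
    with a missing combo-vs-B p-value are dropped from the candidate set and
    counted in ``n_excluded_missing``.
    """
    candidates = sorted(_genes(setB))
    if not candidates:
        return AttenuationResult(frozenset(), frozenset(), None, 0)
    lfc_b = result_B.set_index("gene_id")["log2fc"]
    ab = result_AB_vs_B.set_index("gene_id")
    missing = [g for g in candidates if g not in ab.index or not np.isfinite(ab.loc[g, "pvalue"])]
    kept = [g for g in candidates if g not in set(missing)]
    if not kept:
        return AttenuationResult(frozenset(), frozenset(), None, len(missing))
    pvals = ab.loc[kept, "pvalue"].to_numpy(float)
    padj = bh_adjust(pvals)
    lfc_ab_b = ab.loc[kept, "log2fc"].to_numpy(float)
    signs_b = np.sign(lfc_b.loc[kept].to_numpy(float))
    hit = (padj < alpha) & (np.sign(lfc_ab_b) == -signs_b) & (np.sign(lfc_ab_b) != 0)
    attenuated = frozenset(np.array(kept, dtype=object)[hit])
    return AttenuationResult(
        frozenset(kept), attenuated, len(attenuated) / len(kept), len(missing)
    )
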