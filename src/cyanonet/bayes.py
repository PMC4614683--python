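"""Naive Bayes likelihood-ratio integration of evidence features.

Each feature is discretized into bins calibrated on the gold standard: the
likelihood ratio of a bin is the probability of landing in it for an
interacting (GSP) pair divided by that for a non-interacting (GSN) pair,
with a Laplace pseudocount so every ratio is finite and positive.
Under class-conditional independence the per-feature ratios multiply into a
global likelihood ratio, and

    posterior odds = prior odds x prod_i LR_i(pair)

with prior odds = |GSP| / |GSN| by default. A pair whose posterior odds are
strictly larger than the cutoff (default 5) is a high-confidence
interaction. Features a pair has no value for contribute LR = 1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import Pair, PairSet
from .evidence import FeatureTable
from .gold_standard import GoldStandard

DEFAULT_CUTOFF = 5.0
DEFAULT_N_BINS = 5


@dataclass
class BinScheme:
    """Discretization of one feature: left-closed interval bins or {0,1} levels.

    For continuous features ``boundaries`` are the internal cut points
    b_1 < ... < b_{B-1}; value v maps to bin i such that
    b_i <= v < b_{i+1} (bin 0 is (-inf, b_1), the last bin is [b_{B-1}, inf)).
    Boolean features use two categorical bins {0} and {1}.
    """

    feature_name: str
    boundaries: tuple[float, ...] = ()
    categorical: bool = False

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.boundaries)
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("bin boundaries must be strictly increasing")
        self.boundaries = b

    @property
    def n_bins(self) -> int:
        return 2 if self.categorical else len(self.boundaries) + 1

    def bin_of(self, value: float) -> int:
        if self.categorical:
            if value not in (0, 1):
                raise ValueError(f"{self.feature_name}: non-boolean value {value}")
            return int(value)
        return int(np.searchsorted(self.boundaries, value, side="right"))


def fit_bins(values: Iterable[float], feature_name: str,
             n_bins: int = DEFAULT_N_BINS, boolean: bool = False) -> BinScheme:
    """Quantile bins over the pooled GSP+GSN values (boolean: two levels).

    If the pooled values carry fewer distinct values than requested bins, the
    scheme collapses to distinct-value bins with a warning.
    """
    if boolean:
        return BinScheme(feature_name=feature_name, categorical=True)
    arr = np.asarray(sorted(values), dtype=float)
    if arr.size == 0:
        raise ValueError(f"{feature_name}: no values to fit bins on")
    distinct = np.unique(arr)
    if distinct.size < n_bins:
        warnings.warn(
            f"{feature_name}: only {distinct.size} distinct values; "
            f"collapsing to distinct-value bins")
        # cut between consecutive distinct values
        bounds = (distinct[:-1] + distinct[1:]) / 2 if distinct.size > 1 else ()
        return BinScheme(feature_name=feature_name, boundaries=tuple(bounds))
    qs = np.quantile(arr, np.arange(1, n_bins) / n_bins)
    bounds = tuple(dict.fromkeys(float(q) for q in qs))  # dedupe, keep order
    return BinScheme(feature_name=feature_name, boundaries=bounds)


def fit_lr(feature: FeatureTable, bins: BinScheme, gs: GoldStandard,
           pseudocount: float = 1.0) -> dict[int, float]:
    """Per-bin likelihood ratios calibrated on the gold standard.

    LR(bin) = [(c_pos + a) / (N_pos + aB)] / [(c_neg + a) / (N_neg + aB)]
    with a = pseudocount and B = number of bins. Raises if the feature covers
    no GSP or no GSN pair.
    """
    B = bins.n_bins
    c_pos = np.zeros(B)
    c_neg = np.zeros(B)
    for pair in gs.gsp:
        v = feature.get(pair)
        if v is not None:
            c_pos[bins.bin_of(v)] += 1
    for pair in gs.gsn:
        v = feature.get(pair)
        if v is not None:
            c_neg[bins.bin_of(v)] += 1
    n_pos, n_neg = c_pos.sum(), c_neg.sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"feature {feature.feature_name!r} has no "
            f"{'GSP' if n_pos == 0 else 'GSN'} coverage; cannot calibrate")
    a = float(pseudocount)
    p_pos = (c_pos + a) / (n_pos + a * B)
    p_neg = (c_neg + a) / (n_neg + a * B)
    if a == 0 and ((c_pos == 0) | (c_neg == 0)).any():
        warnings.warn(f"{feature.feature_name}: zero-count bin with pseudocount 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = p_pos / p_neg
    return {i: float(lr[i]) for i in range(B)}


def prior_odds(n_pos: int, n_neg: int) -> float:
    """Prior odds of interaction, estimated as |GSP| / |GSN|."""
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("prior odds need positive GSP and GSN sizes")
    return n_pos / n_neg


@dataclass
class ScoredPair:
    pair: Pair
    feature_lrs: dict[str, float]
    integrated_lr: float
    posterior_odds: float
    is_high_confidence: bool


@dataclass
class LRModel:
    """The trained integrator: per-feature bins + likelihood ratios + prior odds.

    Follows a fit/score style: construct with hyperparameters, call
    :meth:`fit` with feature tables and a gold standard, then :meth:`score`
    or :meth:`score_all` pairs.
    """

    n_bins: int = DEFAULT_N_BINS
    pseudocount: float = 1.0
    cutoff: float = DEFAULT_CUTOFF
    bins: dict[str, BinScheme] = field(default_factory=dict)
    lrs: dict[str, dict[int, float]] = field(default_factory=dict)
    prior_odds: float | None = None

    def fit(self, features: Sequence[FeatureTable], gs: GoldStandard,
            prior: float | None = None) -> "LRModel":
        """Calibrate bins and likelihood ratios on the gold standard.

        Features with no values (e.g. co-expression when no dataset was
        retained) are skipped as uninformative. ``prior`` overrides the
        |GSP|/|GSN| default, e.g. with a genome-wide estimate.
        """
        self.bins = {}
        self.lrs = {}
        for feat in features:
            if len(feat) == 0:
                warnings.warn(f"feature {feat.feature_name!r} empty; skipped")
                continue
            gold_pairs = gs.gsp.pairs | gs.gsn.pairs
            pooled = [v for p, v in feat.values.items() if p in gold_pairs]
            if not pooled:
                warnings.warn(f"feature {feat.feature_name!r} covers no gold pair; skipped")
                continue
            scheme = fit_bins(pooled, feat.feature_name, n_bins=self.n_bins,
                              boolean=feat.is_boolean)
            self.bins[feat.feature_name] = scheme
            self.lrs[feat.feature_name] = fit_lr(feat, scheme, gs,
                                                 pseudocount=self.pseudocount)
        self.prior_odds = prior if prior is not None else prior_odds(
            len(gs.gsp), len(gs.gsn))
        return self

    @property
    def is_fitted(self) -> bool:
        return self.prior_odds is not None

    def feature_lr(self, feature_name: str, value: float | None) -> float:
        """Likelihood ratio contributed by one feature value (1 if missing)."""
        if value is None or feature_name not in self.lrs:
            return 1.0
        scheme = self.bins[feature_name]
        return self.lrs[feature_name][scheme.bin_of(value)]

    def score(self, pair: Pair,
              features: Mapping[str, FeatureTable]) -> ScoredPair:
        """Integrate all feature LRs for one pair into posterior odds."""
        if not self.is_fitted:
            raise RuntimeError("LRModel not fitted")
        lrs = {}
        integrated = 1.0
        for name in self.lrs:
            table = features.get(name)
            value = table.get(pair) if table is not None else None
            lr = self.feature_lr(name, value)
            lrs[name] = lr
            integrated *= lr
        posterior = self.prior_odds * integrated
        return ScoredPair(pair=pair, feature_lrs=lrs, integrated_lr=integrated,
                          posterior_odds=posterior,
                          is_high_confidence=posterior > self.cutoff)

    def score_all(self, features: Sequence[FeatureTable],
                  candidate_pairs: Iterable[Pair] | None = None,
                  exclude: PairSet | None = None) -> list[ScoredPair]:
        """Score candidate pairs, sorted by descending posterior odds.

        With no explicit candidates, every pair holding at least one feature
        value is scored. Gold-standard positives are excluded when given (they
        enter the network with GSP provenance instead). Ties break on the
        canonical pair so the ordering is deterministic.
        """
        by_name = {f.feature_name: f for f in features}
        if candidate_pairs is None:
            cand: set[Pair] = set()
            for f in features:
                cand.update(f.values)
        else:
            cand = set(candidate_pairs)
        if exclude is not None:
            cand -= exclude.pairs
        scored = [self.score(p, by_name) for p in sorted(cand)]
        scored.sort(key=lambda s: (-s.posterior_odds, s.pair))
        return scored

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_bins": self.n_bins,
            "pseudocount": self.pseudocount,
            "cutoff": self.cutoff,
            "prior_odds": self.prior_odds,
            "features": {
                name: {
                    "categorical": self.bins[name].categorical,
                    "boundaries": list(self.bins[name].boundaries),
                    "lrs": {str(k): v for k, v in self.lrs[name].items()},
                }
                for name in sorted(self.lrs)
            },
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "LRModel":
        model = cls(n_bins=d["n_bins"], pseudocount=d["pseudocount"],
                    cutoff=d["cutoff"])
        model.prior_odds = d["prior_odds"]
        for name, spec in d["features"].items():
            model.bins[name] = BinScheme(
                feature_name=name, boundaries=tuple(spec["boundaries"]),
                categorical=spec["categorical"])
            model.lrs[name] = {int(k): v for k, v in spec["lrs"].items()}
        return model

    @classmethod
    def load(cls, path) -> "LRModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def integrate(pair: Pair, lr_model: LRModel,
              features: Mapping[str, FeatureTable]) -> ScoredPair:
    """Posterior odds for one pair under a fitted model (module-level alias)."""
    return lr_model.score(pair, features)


def high_confidence_set(scored: Sequence[ScoredPair]) -> PairSet:
    return PairSet(pairs={s.pair for s in scored if s.is_high_confidence},
                   label="predicted")


def write_scored_pairs(scored: Sequence[ScoredPair], path,
                       feature_names: Sequence[str] | None = None) -> None:
    """TSV: a, b, per-feature LR columns, integrated LR, posterior odds, flag."""
    if feature_names is None:
        names: list[str] = sorted({n for s in scored for n in s.feature_lrs})
    else:
        names = list(feature_names)
    with open(path, "w", encoding="utf-8") as fh:
        cols = ["a", "b"] + [f"lr_{n}" for n in names] + [
            "integrated_lr", "posterior_odds", "high_confidence"]
        fh.write("# " + "\t".join(cols) + "\n")
        for s in scored:
            row = [s.pair.a, s.pair.b]
            row += [f"{s.feature_lrs.get(n, 1.0):.6g}" for n in names]
            row += [f"{s.integrated_lr:.6g}", f"{s.posterior_odds:.6g}",
                    str(int(s.is_high_confidence))]
            fh.write("\t".join(row) + "\n")
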