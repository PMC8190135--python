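"""Abundance, expression and energy arithmetic for phage AMG ecology.

All quantitative claims about phage contributions to sulfur oxidation
reduce to a few ratio computations on per-gene coverage and transcript
tables:

* **community ratio** — summed phage gene coverage over summed phage plus
  host coverage for one gene family in one sample;
* **pair ratio** — the same ratio inside one phage-host pair, normalized by
  the number of phage and host genes so multi-copy families do not bias it;
* **virocell expected ratio** — what the community ratio *should* be if a
  fraction ``v`` of cells are virocells whose phage genes are amplified by
  replication factor ``R``: ``vR/(vR+1)`` with ``R = r/(1-r)`` implied by
  the mean within-pair ratio ``r``;
* **RPKM and condition ratios** — length/depth-normalized expression and
  the hydrothermal:background response of phage AMG transcription;
* **energy budget** — the slice of chemosynthetic energy transformed
  through phage-carried genes: ``E_total * f_pathway * r_phage``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .seq_io import PhyloTree

__all__ = [
    "PhageHostPair",
    "VirocellModel",
    "EnergyBudget",
    "community_ratio",
    "assign_pairs",
    "pair_ratio",
    "expected_community_ratio",
    "rpkm",
    "condition_ratio",
    "condition_ratio_summary",
    "energy_budget",
    "as_percent",
    "UNDEFINED_RATIO",
]

#: sentinel for 0/0 condition ratios
UNDEFINED_RATIO = "undefined"


def as_percent(proportion: float, decimals: int = 1) -> float:
    """Proportion -> percentage rounded half away from zero."""
    x = proportion * 100.0
    scale = 10**decimals
    shifted = x * scale
    rounded = int(shifted + 0.5) if shifted >= 0 else -int(-shifted + 0.5)
    return rounded / scale


# ---------------------------------------------------------------------------
# Coverage ratios
# ---------------------------------------------------------------------------

def community_ratio(
    coverage: pd.DataFrame, sample_id: str, family: str
) -> float:
    """Phage:total gene-coverage proportion for one family in one sample.

    ``coverage`` columns: sample_id, gene_id, source ('phage'/'host'),
    family, coverage.
    """
    sub = coverage[
        (coverage["sample_id"] == sample_id) & (coverage["family"] == family)
    ]
    if sub.empty:
        raise ValueError(f"no genes of family {family!r} in sample {sample_id!r}")
    phage = sub.loc[sub["source"] == "phage", "coverage"].sum()
    host = sub.loc[sub["source"] == "host", "coverage"].sum()
    total = phage + host
    if total == 0:
        raise ValueError("zero total coverage")
    return float(phage / total)


@dataclass
class PhageHostPair:
    """A phage AMG and its host homolog(s) from one sample."""

    sample_id: str
    phage_gene_ids: list[str]
    host_gene_ids: list[str]
    family: str | None = None
    tree_distance: int | None = None  # topological edges
    tie: bool = False

    def __post_init__(self) -> None:
        if not self.phage_gene_ids or not self.host_gene_ids:
            raise ValueError("a pair needs at least one phage and one host gene")


def assign_pairs(
    tree: PhyloTree,
    leaf_metadata: Mapping[str, Mapping[str, str]],
    max_topological_distance: int = 3,
) -> tuple[list[PhageHostPair], list[str]]:
    """Pair phage leaves with their nearest same-sample host leaf.

    Pairing criteria: the two leaves sit on neighboring branches (at most
    ``max_topological_distance`` edges apart) and come from the same sample.
    Ties on topological distance are broken by smaller branch-length
    distance, then lexicographic host label; tied pairs are flagged.
    ``leaf_metadata`` maps leaf label -> {'source': phage|host,
    'sample': ..., optionally 'family' and 'gene_id'}.

    Returns (pairs, unpaired phage leaf labels).
    """
    phage_leaves = sorted(
        l for l in tree.leaf_labels if leaf_metadata[l]["source"] == "phage"
    )
    host_leaves = sorted(
        l for l in tree.leaf_labels if leaf_metadata[l]["source"] == "host"
    )
    pairs: list[PhageHostPair] = []
    unpaired: list[str] = []
    for p in phage_leaves:
        sample = leaf_metadata[p]["sample"]
        candidates = []
        for h in host_leaves:
            if leaf_metadata[h]["sample"] != sample:
                continue
            topo = tree.topological_distance(p, h)
            if topo > max_topological_distance:
                continue
            candidates.append((topo, tree.branch_length_distance(p, h), h))
        if not candidates:
            unpaired.append(p)
            continue
        candidates.sort()
        best = candidates[0]
        tie = len(candidates) > 1 and candidates[1][:2] == best[:2]
        meta_p, meta_h = leaf_metadata[p], leaf_metadata[best[2]]
        pairs.append(
            PhageHostPair(
                sample_id=sample,
                phage_gene_ids=[meta_p.get("gene_id", p)],
                host_gene_ids=[meta_h.get("gene_id", best[2])],
                family=meta_p.get("family"),
                tree_distance=best[0],
                tie=tie,
            )
        )
    return pairs, unpaired


def pair_ratio(pair: PhageHostPair, coverage: pd.DataFrame) -> float:
    """Gene-count-normalized phage:total proportion within one pair.

    mean_p = sum(phage coverages)/n_p; mean_h likewise; the ratio is
    mean_p / (mean_p + mean_h), so duplicating genes with identical
    coverage leaves it unchanged.
    """
    sub = coverage[coverage["sample_id"] == pair.sample_id].set_index("gene_id")
    try:
        cov_p = [float(sub.at[g, "coverage"]) for g in pair.phage_gene_ids]
        cov_h = [float(sub.at[g, "coverage"]) for g in pair.host_gene_ids]
    except KeyError as exc:
        raise ValueError(f"coverage missing for pair gene {exc}") from exc
    mean_p = sum(cov_p) / len(cov_p)
    mean_h = sum(cov_h) / len(cov_h)
    if mean_p + mean_h == 0:
        raise ValueError("zero coverage on both sides of the pair")
    return mean_p / (mean_p + mean_h)


# ---------------------------------------------------------------------------
# Virocell model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VirocellModel:
    """Community-level virocell parameters.

    ``v``: fraction of cells in a virocell (infected) state; ``r``: mean
    within-pair phage:total coverage ratio, implying a per-virocell
    phage:host gene abundance factor ``R = r/(1-r)``.
    """

    v: float
    r: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.v <= 1.0:
            raise ValueError("v must be in [0, 1]")
        if not 0.0 <= self.r < 1.0:
            raise ValueError("r must be in [0, 1)")

    @property
    def R(self) -> float:
        return self.r / (1.0 - self.r)


def expected_community_ratio(model: VirocellModel, literal: bool = False) -> float:
    """Expected community phage:total ratio under the virocell model.

    The implemented reading treats phage coverage ``v*R`` (virocell fraction
    times per-virocell phage gene amplification) against host coverage 1
    contributed by every cell: ``vR/(vR+1)``.  At ``v=1`` this returns ``r``
    exactly.  ``literal=True`` computes the plain product ``v*r`` instead;
    it is retained for comparison but understates the expectation because it
    ignores that only infected cells carry phage genes.
    """
    if literal:
        return model.v * model.r
    vr = model.v * model.R
    return vr / (vr + 1.0)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def rpkm(count: float, gene_length_bp: float, library_size: float) -> float:
    """Reads per kilobase of gene per million mapped reads."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if gene_length_bp <= 0:
        raise ValueError("gene_length_bp must be positive")
    return count / (library_size / 1e6) / (gene_length_bp / 1e3)


def condition_ratio(
    rpkm_treatment: float, rpkm_background: float
) -> float | str:
    """Treatment:background expression ratio with explicit sentinels.

    Positive numerator over zero denominator yields +infinity (the host or
    background transcript abundance is zero); 0/0 is undefined.
    """
    if rpkm_treatment < 0 or rpkm_background < 0:
        raise ValueError("RPKM values must be nonnegative")
    if rpkm_background == 0:
        return math.inf if rpkm_treatment > 0 else UNDEFINED_RATIO
    return rpkm_treatment / rpkm_background


def condition_ratio_summary(
    ratios: Sequence[float | str],
) -> dict:
    """Mean over finite ratios; infinite/undefined cases counted, not averaged."""
    finite = [r for r in ratios if isinstance(r, float) and math.isfinite(r)]
    n_inf = sum(1 for r in ratios if r == math.inf)
    n_undef = sum(1 for r in ratios if r == UNDEFINED_RATIO)
    return {
        "mean_ratio": sum(finite) / len(finite) if finite else None,
        "n_finite": len(finite),
        "n_infinite": n_inf,
        "n_undefined": n_undef,
    }


# ---------------------------------------------------------------------------
# Energy budget
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnergyBudget:
    E_total: float  # J/kg available for microbial metabolism
    f_pathway: float  # fraction derived from the pathway (sulfur oxidation)
    r_phage: float  # phage:total gene coverage ratio
    E_phage_raw: float  # exact product, J/kg
    E_phage: float  # headline value, 2 significant figures


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, -exponent + sig - 1)


def energy_budget(
    E_total: float, f_pathway: float, r_phage: float
) -> EnergyBudget:
    """Partition an energy budget down to the phage-transformed slice.

    ``E_phage = E_total * f_pathway * r_phage``; the headline field is
    rounded to two significant figures (e.g. 3900 * 0.83 * 0.10 = 323.7,
    headline 320 J/kg).
    """
    if min(E_total, f_pathway, r_phage) < 0:
        raise ValueError("all inputs must be nonnegative")
    if max(f_pathway, r_phage) > 1:
        raise ValueError("proportions must be at most 1")
    raw = E_total * f_pathway * r_phage
    return EnergyBudget(
        E_total=E_total,
        f_pathway=f_pathway,
        r_phage=r_phage,
        E_phage_raw=raw,
        E_phage=_round_sig(raw, 2),
    )
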