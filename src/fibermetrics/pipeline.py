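"""High-level orchestration: full bidirectional comparison of two networks."""

from __future__ import annotations

from dataclasses import dataclass

from .connectivity import ConnectivityResult, connectivity_rates
from .geometry import GeometryResult, compute_metric, cull_fibers
from .model import MetricConfig, Network

__all__ = ["ComparisonReport", "compare_networks"]


@dataclass
class ComparisonReport:
    """The four normalized rates plus the detailed per-direction results."""

    gfnr: float
    gfpr: float
    cfnr: float
    cfpr: float
    geo_gt: GeometryResult  # GT measured against test (false negatives)
    geo_t: GeometryResult  # test measured against GT (false positives)
    conn: ConnectivityResult

    def rates(self) -> dict[str, float]:
        return {"gfnr": self.gfnr, "gfpr": self.gfpr,
                "cfnr": self.cfnr, "cfpr": self.cfpr}


def compare_networks(gt: Network, test: Network, config: MetricConfig) -> ComparisonReport:
    """Compute GFNR/GFPR and CFNR/CFPR for a ground-truth/test pair."""
    geo_gt = compute_metric(gt, test, config)
    geo_t = compute_metric(test, gt, config)
    conn = connectivity_rates(gt, test, config, geo_gt=geo_gt, geo_t=geo_t)
    return ComparisonReport(
        gfnr=geo_gt.global_M,
        gfpr=geo_t.global_M,
        cfnr=conn.cfnr,
        cfpr=conn.cfpr,
        geo_gt=geo_gt,
        geo_t=geo_t,
        conn=conn,
    )


def cull_and_recompare(gt: Network, test: Network, config: MetricConfig,
                       threshold: float = 0.9) -> tuple[Network, ComparisonReport]:
    """Drop test fibers with mean error above ``threshold`` and re-measure.

    The incomplete-ground-truth workflow: correctly segmented fibers with
    no counterpart in a partial ground truth would otherwise dominate the
    false-positive rate.
    """
    geo_t = compute_metric(test, gt, config)
    culled = cull_fibers(test, geo_t, threshold)
    return culled, compare_networks(gt, culled, config)
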