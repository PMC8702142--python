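"""LR-distribution simulation studies across relationship degrees and
panel completeness.

For a scenario (relationship, replicate count, kinship-panel fraction) two
arms are simulated: truth = related (gene-dropped genotypes under the
relationship's template pedigree) and truth = unrelated (two independent
individuals).  Each replicate's pairwise log10 LR tests the scenario's
hypothesis against unrelatedness; the distributions, exceedance fractions
at log10 LR thresholds 0 and 4, and arm-overlap summaries quantify how
informative the panel is for that degree of relatedness.

Replicates are batched through the likelihood engine; partial-panel
replicates are realised by masking an independent random subset of kinship
markers per replicate, which is equivalent to subsampling (skipped markers
emit no information, linkage spans them correctly).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import haldane_theta
from .kinship import pairwise_log10_lr, prepare_markers
from .panel import PanelManifest
from .pedigree import RELATIONSHIPS, relationship_template

__all__ = ["ScenarioSpec", "LRDistribution", "run_scenario", "overlap_summary",
           "export_distributions"]

THRESHOLDS = (0.0, 4.0)


@dataclass(frozen=True)
class ScenarioSpec:
    relationship: str
    n_reps: int = 500
    panel_fraction: float = 1.0
    population: str = "EUR"
    seed: int = 0

    def __post_init__(self):
        if self.relationship not in RELATIONSHIPS or self.relationship == "unrelated":
            raise ValueError(f"bad relationship {self.relationship!r}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not (0 < self.panel_fraction <= 1):
            raise ValueError("panel_fraction must be in (0, 1]")


@dataclass
class LRDistribution:
    spec: ScenarioSpec
    related: np.ndarray  # log10 LR samples, truth = related
    unrelated: np.ndarray  # log10 LR samples, truth = unrelated

    def exceedance(self, arm: str, threshold: float) -> float:
        x = getattr(self, arm)
        return float((x >= threshold).mean())

    def summary(self) -> pd.DataFrame:
        rows = []
        for arm in ("related", "unrelated"):
            x = getattr(self, arm)
            q = np.quantile(x, [0.01, 0.25, 0.5, 0.75, 0.99])
            rows.append(
                {
                    "arm": arm,
                    "n": len(x),
                    "median": q[2],
                    "q01": q[0], "q25": q[1], "q75": q[3], "q99": q[4],
                    **{f"exceed_log10lr_{int(t)}": self.exceedance(arm, t)
                       for t in THRESHOLDS},
                }
            )
        return pd.DataFrame(rows)


def _simulate_pair_dosages(
    relationship: str, markers: pd.DataFrame, n_reps: int, rng,
    related: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched gene dropping of the two typed individuals of a template.

    Founder haplotypes are iid Bernoulli(freq); meioses recombine with the
    Haldane switch probability per inter-marker gap, independently per
    replicate.  Returns dosage arrays (n_reps, n_markers) for A and B.
    """
    ped, a_id, b_id = relationship_template(
        "unrelated" if not related else relationship
    )
    n = len(markers)
    freq = markers["freq"].to_numpy()
    chrom = markers["chrom"].to_numpy()
    pos = markers["pos_cm"].to_numpy()
    theta = np.zeros(n)
    new_chrom = np.ones(n, dtype=bool)
    for ch in pd.unique(chrom):
        idx = np.flatnonzero(chrom == ch)
        theta[idx[1:]] = haldane_theta(np.diff(pos[idx]))
        new_chrom[idx[1:]] = False

    haps: dict[str, np.ndarray] = {}  # iid -> (n_reps, n, 2)
    order = ped.topo_order()
    for iid in order:
        ind = ped.members[iid]
        if ind.is_founder:
            haps[iid] = (rng.random((n_reps, n, 2)) < freq[None, :, None]).astype(
                np.int8
            )
        else:
            g = np.empty((n_reps, n, 2), dtype=np.int8)
            for col, parent in ((0, ind.father), (1, ind.mother)):
                sw = rng.random((n_reps, n)) < theta[None, :]
                # chromosome starts draw a fresh 50/50 phase
                sw[:, new_chrom] = rng.random((n_reps, int(new_chrom.sum()))) < 0.5
                choice = np.empty((n_reps, n), dtype=np.int8)
                starts = np.flatnonzero(new_chrom)
                for s0, s1 in zip(starts, list(starts[1:]) + [n]):
                    choice[:, s0:s1] = np.bitwise_xor.accumulate(
                        sw[:, s0:s1].astype(np.int8), axis=1
                    )
                ph = haps[parent]
                g[:, :, col] = np.take_along_axis(
                    ph, choice[:, :, None].astype(np.int64), axis=2
                )[:, :, 0]
            haps[iid] = g
    return haps[a_id].sum(axis=2), haps[b_id].sum(axis=2)


def run_scenario(
    spec: ScenarioSpec, panel: PanelManifest, *, error_rate: float = 0.0
) -> LRDistribution:
    """Simulate both truth arms of a scenario and collect log10 LRs."""
    markers = prepare_markers(panel, spec.population)
    rng = np.random.default_rng(spec.seed)
    arms = {}
    for arm, related in (("related", True), ("unrelated", False)):
        dA, dB = _simulate_pair_dosages(
            spec.relationship, markers, spec.n_reps, rng, related
        )
        if spec.panel_fraction < 1.0:
            n = len(markers)
            n_keep = round(spec.panel_fraction * n)
            for b in range(spec.n_reps):
                drop = rng.choice(n, size=n - n_keep, replace=False)
                dA[b, drop] = -1
                dB[b, drop] = -1
        arms[arm] = np.asarray(
            pairwise_log10_lr(
                dA, dB, spec.relationship, markers, error_rate=error_rate
            )
        )
    return LRDistribution(spec, arms["related"], arms["unrelated"])


def overlap_summary(dist: LRDistribution) -> dict[str, float]:
    """Arm overlap: fraction of each arm crossing the other arm's 99th /
    1st percentile."""
    if len(dist.related) == 0 or len(dist.unrelated) == 0:
        raise ValueError("both arms must be non-empty")
    u99 = np.quantile(dist.unrelated, 0.99)
    r01 = np.quantile(dist.related, 0.01)
    return {
        "related_below_unrelated_q99": float((dist.related < u99).mean()),
        "unrelated_above_related_q01": float((dist.unrelated > r01).mean()),
    }


def export_distributions(dist: LRDistribution, out_dir: str | Path) -> dict[str, Path]:
    """Write per-replicate samples, the summary table, and a density plot."""
    if len(dist.related) == 0 or len(dist.unrelated) == 0:
        raise ValueError("both arms must be non-empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"{dist.spec.relationship}_f{dist.spec.panel_fraction:g}"
    samples = pd.DataFrame(
        {
            "arm": ["related"] * len(dist.related)
            + ["unrelated"] * len(dist.unrelated),
            "log10_lr": np.concatenate([dist.related, dist.unrelated]),
        }
    )
    samples_path = out / f"{tag}_samples.tsv"
    samples.to_csv(samples_path, sep="\t", index=False)
    summary_path = out / f"{tag}_summary.tsv"
    dist.summary().to_csv(summary_path, sep="\t", index=False)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    bins = np.histogram_bin_edges(samples["log10_lr"], bins=40)
    for arm, color in (("related", "tab:blue"), ("unrelated", "tab:orange")):
        ax.hist(
            getattr(dist, arm), bins=bins, density=True, alpha=0.6,
            label=arm, color=color,
        )
    ax.axvline(4.0, ls="--", c="k", lw=0.8)
    ax.set_xlabel("log10 LR")
    ax.set_ylabel("density")
    ax.set_title(f"{dist.spec.relationship} (fraction {dist.spec.panel_fraction:g})")
    ax.legend()
    plot_path = out / f"{tag}_density.png"
    fig.savefig(plot_path, dpi=120)
    plt.close(fig)
    return {"samples": samples_path, "summary": summary_path, "plot": plot_path}
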