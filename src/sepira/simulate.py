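"""Synthetic multi-tissue compendia with planted regulons and activities.

The generator encodes the structural assumptions the method exploits, not
the empirical distributions of any real compendium:

* a handful of tissue-specific TFs whose (mostly activating) regulons are
  driven by a per-sample latent activity, high in the target tissue (and in
  a couple of private secondary tissues — tissue-specific regulators are
  rarely exclusive to a single tissue) and zero elsewhere;
* "immune-confounder" TFs active in the target tissue *and* in the
  immune-rich guard tissues (blood, spleen) — the failure mode the guard
  contrast exists to reject;
* background TFs with no planted regulon, plus free noise genes and
  near-constant stable genes (fodder for the variance filter);
* promoter beta-values generated on the logit scale so that activating
  targets are hypomethylated when their TF is active.

Defaults describe a compendium of 10 tissues x 10 samples with 3 specific
TFs of 40 signed targets each (5% repressed) at noise SD 0.5. The planted
activation (``activity_high`` = 3 on the log2 scale, target effect size 2,
each TF active in 3 of 10 tissues) makes marginal TF-target correlations
~0.95 — a strongly tissue-specific regulon, which is what the
effective-sample-size Bonferroni null demands of any detectable edge at
this scale — while keeping the TFs' activity profiles decorrelated enough
for the partial-correlation pruning to assign shared candidate targets
correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .datatypes import (
    ExpressionMatrix,
    ProbeAnnotation,
    ProbeMethylationMatrix,
    RegulatoryNetwork,
)

__all__ = ["GroundTruth", "SimConfig", "simulate_dnam", "simulate_expression"]

TARGET_TISSUE = "lung"
GUARD_TISSUES = ("blood", "spleen")


@dataclass
class SimConfig:
    """Generator settings; defaults are the reference study conditions."""

    n_tissues: int = 10
    samples_per_tissue: int = 10
    n_tfs_specific: int = 3
    n_tfs_background: int = 5
    targets_per_tf: int = 40
    frac_repressed: float = 0.05
    effect_size: float = 2.0
    noise_sd: float = 0.5
    n_noise_genes: int = 200
    n_stable_genes: int = 50
    guard_confounders: int = 2
    seed: int = 0
    # latent-activity and TF-transcript parameters
    activity_high: float = 3.0
    active_jitter_sd: float = 0.5
    n_secondary_tissues: int = 2
    tf_coupling: float = 1.5
    tf_noise_sd: float = 0.2
    baseline: float = 5.0
    # promoter methylation parameters (logit scale)
    dnam_effect: float = 1.0
    dnam_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        counts = (
            self.n_tissues,
            self.samples_per_tissue,
            self.n_tfs_specific,
            self.n_tfs_background,
            self.targets_per_tf,
            self.n_noise_genes,
            self.n_stable_genes,
            self.guard_confounders,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.samples_per_tissue < 2:
            raise ValueError("need at least 2 samples per tissue")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0.0 <= self.frac_repressed <= 1.0):
            raise ValueError("frac_repressed must lie in [0, 1]")
        if self.guard_confounders > 0 and self.n_tissues < 3:
            raise ValueError("guard confounders require >= 3 tissues (target + 2 guards)")
        if self.n_secondary_tissues < 0:
            raise ValueError("n_secondary_tissues must be >= 0")

    @property
    def tissue_labels(self) -> list[str]:
        labels = [TARGET_TISSUE]
        if self.n_tissues >= 2:
            labels.append(GUARD_TISSUES[0])
        if self.n_tissues >= 3:
            labels.append(GUARD_TISSUES[1])
        labels += [f"tissue{i:02d}" for i in range(4, self.n_tissues + 1)]
        return labels


@dataclass
class GroundTruth:
    """Planted regulons and per-sample activities of the simulated TFs."""

    true_network: RegulatoryNetwork
    true_activity: pd.DataFrame  # TFs x samples


def _planted_signs(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    n_rep = int(round(cfg.frac_repressed * cfg.targets_per_tf))
    signs = np.ones(cfg.targets_per_tf, dtype=int)
    if n_rep:
        signs[rng.choice(cfg.targets_per_tf, size=n_rep, replace=False)] = -1
    return signs


def simulate_expression(cfg: SimConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate a log2-scale expression compendium plus its ground truth.

    Reproducible under ``cfg.seed``; one private RNG stream, no global state.
    """
    rng = np.random.default_rng(cfg.seed)
    tissues = cfg.tissue_labels
    samples, sample_tissue = [], []
    for t in tissues:
        for i in range(cfg.samples_per_tissue):
            samples.append(f"{t}_s{i:02d}")
            sample_tissue.append(t)
    tissue_arr = np.asarray(sample_tissue)
    n_samples = len(samples)

    spec_tfs = [f"TF_SP{i:02d}" for i in range(1, cfg.n_tfs_specific + 1)]
    conf_tfs = [f"TF_IM{i:02d}" for i in range(1, cfg.guard_confounders + 1)]
    bg_tfs = [f"TF_BG{i:02d}" for i in range(1, cfg.n_tfs_background + 1)]

    # each specific TF is active in the target tissue plus a few private
    # secondary tissues (disjoint across TFs, round-robin over the non-guard
    # pool); confounders are active in the target AND the guard tissues
    pool = [t for t in tissues if t not in (TARGET_TISSUE,) + GUARD_TISSUES]
    active_tissues: dict[str, set[str]] = {}
    k = 0
    for tf in spec_tfs:
        chosen = {TARGET_TISSUE}
        for _ in range(cfg.n_secondary_tissues):
            if k < len(pool):
                chosen.add(pool[k])
                k += 1
        active_tissues[tf] = chosen
    active_tissues.update({tf: {TARGET_TISSUE, *GUARD_TISSUES} for tf in conf_tfs})

    planted = spec_tfs + conf_tfs
    activity = np.empty((len(planted), n_samples))
    for i, tf in enumerate(planted):
        on = np.isin(tissue_arr, sorted(active_tissues[tf]))
        jitter = rng.normal(0.0, cfg.active_jitter_sd, n_samples)
        activity[i] = np.where(on, cfg.activity_high + jitter, 0.0)

    rows: dict[str, np.ndarray] = {}
    edges: dict[str, dict[str, int]] = {}
    for i, tf in enumerate(planted):
        rows[tf] = (
            cfg.baseline
            + cfg.tf_coupling * activity[i]
            + rng.normal(0.0, cfg.tf_noise_sd, n_samples)
        )
    for tf in bg_tfs:
        rows[tf] = cfg.baseline + rng.normal(0.0, cfg.noise_sd, n_samples)

    gene_counter = 0
    for i, tf in enumerate(planted):
        signs = _planted_signs(rng, cfg)
        edges[tf] = {}
        for sign in signs:
            gene_counter += 1
            gene = f"G{gene_counter:04d}"
            edges[tf][gene] = int(sign)
            base_g = rng.uniform(3.0, 7.0)
            rows[gene] = (
                base_g
                + sign * cfg.effect_size * activity[i]
                + rng.normal(0.0, cfg.noise_sd, n_samples)
            )
    for j in range(1, cfg.n_noise_genes + 1):
        rows[f"N{j:04d}"] = rng.uniform(3.0, 7.0) + rng.normal(0.0, cfg.noise_sd, n_samples)
    for j in range(1, cfg.n_stable_genes + 1):
        rows[f"S{j:04d}"] = rng.uniform(3.0, 7.0) + rng.normal(0.0, 0.05, n_samples)

    values = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    values.index.name = "gene_id"
    expr = ExpressionMatrix(values, pd.Series(sample_tissue, index=samples))
    truth = GroundTruth(
        true_network=RegulatoryNetwork(edges),
        true_activity=pd.DataFrame(activity, index=planted, columns=samples),
    )
    return expr, truth


def simulate_dnam(
    cfg: SimConfig, truth: GroundTruth
) -> tuple[ProbeMethylationMatrix, ProbeAnnotation]:
    """Promoter beta-values for the planted target genes.

    Each target gene gets 1-3 signal probes whose beta is
    inverse-logit(b0 - sign * dnam_effect * activity + noise): activating
    targets are hypomethylated when the TF is active. ~10% of genes carry
    their signal on FirstExon probes and ~5% on TSS1500 probes only, to
    exercise the fallback; genes with TSS200 probes additionally get decoy
    lower-priority probes of pure noise, plus two "Other"-class-only decoy
    genes that the summarizer must omit.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    net = truth.true_network
    act = truth.true_activity
    samples = act.columns
    n_samples = len(samples)

    # per-gene signed drive: sum of sign * activity over regulating TFs
    drive: dict[str, np.ndarray] = {}
    for tf in net.tf_ids:
        for gene, sign in net.edges[tf].items():
            drive[gene] = drive.get(gene, 0.0) + sign * act.loc[tf].to_numpy()

    probe_rows: dict[str, np.ndarray] = {}
    ann_rows: list[tuple[str, str, str]] = []
    probe_counter = 0

    def new_probe(gene: str, region: str, values: np.ndarray) -> None:
        nonlocal probe_counter
        probe_counter += 1
        pid = f"cg{probe_counter:06d}"
        probe_rows[pid] = values
        ann_rows.append((pid, gene, region))

    for gene in sorted(drive):
        u = rng.uniform()
        signal_region = "TSS200" if u < 0.85 else ("FirstExon" if u < 0.95 else "TSS1500")
        b0 = rng.uniform(-1.0, 1.0)
        for _ in range(int(rng.integers(1, 4))):
            offset = rng.normal(0.0, 0.3)
            logit = (
                b0
                + offset
                - cfg.dnam_effect * drive[gene]
                + rng.normal(0.0, cfg.dnam_noise_sd, n_samples)
            )
            new_probe(gene, signal_region, expit(logit))
        if signal_region == "TSS200":
            for _ in range(int(rng.integers(0, 3))):
                decoy_region = str(rng.choice(["FirstExon", "TSS1500", "Other"]))
                new_probe(gene, decoy_region, expit(rng.normal(0.0, 1.0, n_samples)))
    # decoy genes with probes only in class "Other": must be omitted downstream
    for decoy_gene in ("DECOY_OTHER1", "DECOY_OTHER2"):
        new_probe(decoy_gene, "Other", expit(rng.normal(0.0, 1.0, n_samples)))

    betas = pd.DataFrame.from_dict(probe_rows, orient="index", columns=samples)
    betas.index.name = "probe_id"
    ann = pd.DataFrame(ann_rows, columns=["probe_id", "gene_id", "region_class"])
    return ProbeMethylationMatrix(betas), ProbeAnnotation(ann)
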