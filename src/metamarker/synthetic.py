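"""Synthetic two-group metabolomic matrices with planted marker structure.

The generator emulates the statistical shape the pipeline assumes: positive
peak-area abundances with log-normal marginals, block correlation among
control metabolites (metabolites in a shared pathway co-vary), and two kinds
of planted ground truth —

* *primary* markers: the case group's log-mean is shifted by a configured
  number of control log-SDs (a concentration-shift marker);
* *secondary* markers: case values are resampled independently from the
  metabolite's own marginal distribution, so the level is untouched but
  every correlation to the rest of the block is severed (a
  correlation-break marker).

Missing cells are knocked out completely at random.  The default shape
mirrors a 27-control / 12-case cohort over 210 metabolites.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .enrichment import PathwayAnnotation, write_annotation
from .io_prep import CASE, CONTROL, MetabolomicMatrix, write_matrix

logger = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    """Generator settings.

    ``primary_markers`` maps metabolite index -> shift in control log-SD
    units; ``secondary_markers`` lists indices whose case values are
    decoupled from their block.  ``block_sizes=None`` auto-partitions about
    80% of metabolites into blocks of 8.
    """

    n_control: int = 27
    n_case: int = 12
    n_metabolites: int = 210
    block_sizes: list[int] | None = None
    within_block_correlation: float = 0.6
    primary_markers: dict[int, float] = field(default_factory=dict)
    secondary_markers: list[int] = field(default_factory=list)
    missing_rate: float = 0.02
    log_mean_range: tuple[float, float] = (6.0, 14.0)
    log_sd_range: tuple[float, float] = (0.3, 0.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.within_block_correlation < 1:
            raise ValueError("within_block_correlation must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for idx in list(self.primary_markers) + list(self.secondary_markers):
            if not 0 <= idx < self.n_metabolites:
                raise ValueError(f"planted index {idx} out of range")
        if self.block_sizes is None:
            n_blocked = int(0.8 * self.n_metabolites)
            self.block_sizes = [8] * (n_blocked // 8)
        if sum(self.block_sizes) > self.n_metabolites:
            raise ValueError("blocks exceed the number of metabolites")


def _blocks(cfg: SyntheticConfig) -> list[list[int]]:
    blocks, start = [], 0
    for size in cfg.block_sizes:
        blocks.append(list(range(start, start + size)))
        start += size
    return blocks


def generate(cfg: SyntheticConfig) -> tuple[MetabolomicMatrix, dict]:
    """Draw a two-group matrix and its ground-truth manifest.

    Both groups share the control-group multivariate log-normal law; cases
    then receive the primary shifts and secondary marginal resampling.
    Deterministic for a given ``cfg.seed``.
    """
    dual = set(cfg.primary_markers) & set(cfg.secondary_markers)
    if dual:
        logger.info("indices planted as both primary and secondary: %s", sorted(dual))
    rng = np.random.default_rng(cfg.seed)
    p = cfg.n_metabolites
    mu = rng.uniform(*cfg.log_mean_range, size=p)
    sd = rng.uniform(*cfg.log_sd_range, size=p)
    blocks = _blocks(cfg)

    n_total = cfg.n_control + cfg.n_case
    # block-structured correlated standard normals, then affine to (mu, sd)
    z = rng.standard_normal((n_total, p))
    rho = cfg.within_block_correlation
    for block in blocks:
        shared = rng.standard_normal(n_total)
        z[:, block] = np.sqrt(rho) * shared[:, None] + np.sqrt(1 - rho) * z[:, block]
    log_vals = mu + sd * z

    ctrl = log_vals[: cfg.n_control]
    case = log_vals[cfg.n_control :]
    for idx, shift in cfg.primary_markers.items():
        case[:, idx] = case[:, idx] + shift * sd[idx]
    for idx in cfg.secondary_markers:
        case[:, idx] = rng.normal(mu[idx], sd[idx], size=cfg.n_case)

    values = np.exp(np.vstack([ctrl, case]))
    if cfg.missing_rate > 0:
        knockout = rng.random(values.shape) < cfg.missing_rate
        values[knockout] = np.nan

    width = len(str(p))
    metabolite_ids = [f"M{j + 1:0{width}d}" for j in range(p)]
    sample_ids = [f"S{i + 1:03d}" for i in range(n_total)]
    group = np.array([CONTROL] * cfg.n_control + [CASE] * cfg.n_case, dtype=object)
    m = MetabolomicMatrix(sample_ids, group, metabolite_ids, values)
    manifest = {
        "seed": cfg.seed,
        "n_control": cfg.n_control,
        "n_case": cfg.n_case,
        "n_metabolites": p,
        "within_block_correlation": rho,
        "blocks": [[metabolite_ids[j] for j in b] for b in blocks],
        "primary_markers": {
            metabolite_ids[j]: s for j, s in cfg.primary_markers.items()
        },
        "secondary_markers": [metabolite_ids[j] for j in cfg.secondary_markers],
        "dual_status": sorted(metabolite_ids[j] for j in dual),
        "missing_rate": cfg.missing_rate,
    }
    return m, manifest


def block_annotation(manifest: dict) -> list[PathwayAnnotation]:
    """Toy pathway annotation with one pathway per correlated block."""
    return [
        PathwayAnnotation(f"block{i + 1:02d}", f"synthetic block {i + 1}", frozenset(b))
        for i, b in enumerate(manifest["blocks"])
    ]


def write_fixture(
    m: MetabolomicMatrix, manifest: dict, out_dir: str | Path
) -> dict[str, Path]:
    """Write matrix.tsv, truth.json and a block-aligned pathways.gmt."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.tsv",
        "truth": out / "truth.json",
        "pathways": out / "pathways.gmt",
    }
    write_matrix(m, paths["matrix"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    write_annotation(block_annotation(manifest), paths["pathways"])
    return paths
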