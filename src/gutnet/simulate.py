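"""Synthetic genus-count, pathway and phenotype generator.

The generator emulates the statistical structure of a three-arm rodent
hypertension study read out by 16S amplicon sequencing: ``n_groups`` groups of
``n_samples_per_group`` animals, a genus-level count table with a long-tailed
abundance distribution, group-specific correlation blocks among genera,
planted enriched/suppressed genera, pathway abundances mixed from taxa, and
continuous phenotypes (blood pressure, trabecular bone measures) linked to
planted taxa.

Model
-----
Counts follow a logistic-normal / multinomial composition model.  For sample
``i`` in group ``g``::

    z_i ~ MVN(0, C_g)          block-structured correlation, unit variances
    eta_i = mu + ln(2) * effect[:, g] + z_i
    p_i = softmax(eta_i)
    counts_i ~ Multinomial(sequencing_depth, p_i)

``mu`` is a per-taxon baseline drawn once from a normal on the latent log
scale (``baseline_log_sd`` controls the abundance skew: a few dominant genera
and a long tail).  ``C_g`` is block-diagonal with compound-symmetric blocks
(``within_rho`` inside a block, zero outside).  Effects are applied on the
latent log scale so ``log2_effect`` is interpretable as an approximate log2
fold change of relative abundance for non-dominant taxa.

Phenotypes are linear in the centered log-ratio (clr) abundance of their
linked taxon plus a group shift and Gaussian noise; pathways are non-negative
mixtures of random taxon subsets with multiplicative lognormal noise.

Reproducibility
---------------
One global ``seed`` feeds a fixed per-operation stream-splitting scheme
(:func:`numpy.random.SeedSequence` with a distinct ``spawn_key`` per
operation), so each generator operation is individually reproducible and
independent of call order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import CountTable, GutnetError, OmicsBlock

__all__ = [
    "SyntheticConfig",
    "PhenotypeSpec",
    "generate_counts",
    "generate_phenotypes",
    "generate_pathways",
    "study_config",
    "clr_transform",
]

# spawn keys of the per-operation random streams
_STREAM_BASELINE = 0
_STREAM_COUNTS = 1
_STREAM_PHENOTYPES = 2
_STREAM_PATHWAYS = 3


class ConfigError(GutnetError):
    """Invalid synthetic-data configuration."""


@dataclass
class PhenotypeSpec:
    """One continuous phenotype: optional taxon link, slope, noise, group shifts."""

    name: str
    linked_taxon_index: int | None
    slope: float
    noise_sd: float
    group_shift: tuple[float, ...]


@dataclass
class SyntheticConfig:
    """Full description of one synthetic study.

    ``block_spec[g]`` is a list of ``(block_size, within_rho)`` pairs for
    group ``g``; blocks occupy consecutive taxon indices starting at 0.
    ``effect_spec`` entries are ``(taxon_index, group_index, log2_effect)``.
    """

    n_groups: int = 3
    n_samples_per_group: int = 8
    n_taxa: int = 200
    sequencing_depth: int = 20_000
    block_spec: list[list[tuple[int, float]]] = field(default_factory=list)
    effect_spec: list[tuple[int, int, float]] = field(default_factory=list)
    phenotype_spec: list[PhenotypeSpec] = field(default_factory=list)
    baseline_log_sd: float = 2.0
    n_pathways: int = 20
    pathway_k: int = 5
    pathway_noise_sd: float = 0.2
    pathway_spec: list[tuple[str, dict[int, float]]] | None = None
    group_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 2:
            raise ConfigError("n_samples_per_group must be >= 2")
        if self.n_groups < 1:
            raise ConfigError("n_groups must be >= 1")
        if self.sequencing_depth < 1:
            raise ConfigError("sequencing_depth must be >= 1")
        if not self.block_spec:
            self.block_spec = [[] for _ in range(self.n_groups)]
        if len(self.block_spec) != self.n_groups:
            raise ConfigError("block_spec must have one entry per group")
        for g, blocks in enumerate(self.block_spec):
            total = sum(size for size, _ in blocks)
            if total > self.n_taxa:
                raise ConfigError(
                    f"group {g}: block sizes sum to {total} > n_taxa={self.n_taxa}"
                )
            for size, rho in blocks:
                if size > self.n_taxa:
                    raise ConfigError(f"block of size {size} exceeds n_taxa={self.n_taxa}")
                if not _compound_symmetric_psd(size, rho):
                    raise ConfigError(
                        f"block (size={size}, rho={rho}) is not positive semi-definite"
                    )
        for taxon, group, _ in self.effect_spec:
            if not (0 <= taxon < self.n_taxa):
                raise ConfigError(f"effect taxon index {taxon} out of range")
            if not (0 <= group < self.n_groups):
                raise ConfigError(f"effect group index {group} out of range")
        for spec in self.phenotype_spec:
            if spec.linked_taxon_index is not None and not (
                0 <= spec.linked_taxon_index < self.n_taxa
            ):
                raise ConfigError(
                    f"phenotype {spec.name!r}: linked taxon index "
                    f"{spec.linked_taxon_index} out of range"
                )
            if len(spec.group_shift) != self.n_groups:
                raise ConfigError(
                    f"phenotype {spec.name!r}: group_shift needs {self.n_groups} entries"
                )
        if self.pathway_spec is not None:
            for name, weights in self.pathway_spec:
                for taxon, w in weights.items():
                    if not (0 <= taxon < self.n_taxa):
                        raise ConfigError(f"pathway {name!r}: taxon index {taxon} out of range")
                    if w < 0:
                        raise ConfigError(f"pathway {name!r}: negative mixing weight")
        if self.group_names is None:
            self.group_names = tuple(f"group{g}" for g in range(self.n_groups))
        elif len(self.group_names) != self.n_groups:
            raise ConfigError("group_names must have one entry per group")

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["phenotype_spec"] = [asdict(p) for p in self.phenotype_spec]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        d["block_spec"] = [
            [tuple(b) for b in blocks] for blocks in d.get("block_spec") or []
        ]
        d["effect_spec"] = [tuple(e) for e in d.get("effect_spec") or []]
        d["phenotype_spec"] = [
            PhenotypeSpec(**{**p, "group_shift": tuple(p["group_shift"])})
            for p in d.get("phenotype_spec") or []
        ]
        if d.get("group_names") is not None:
            d["group_names"] = tuple(d["group_names"])
        if d.get("pathway_spec") is not None:
            d["pathway_spec"] = [
                (name, {int(t): float(w) for t, w in weights.items()})
                for name, weights in d["pathway_spec"]
            ]
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


def _compound_symmetric_psd(size: int, rho: float) -> bool:
    # eigenvalues of (1-rho) I + rho J are 1 + (size-1) rho and 1 - rho
    if size < 1:
        return False
    return (1.0 - rho) >= -1e-12 and (1.0 + (size - 1) * rho) >= -1e-12


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,))
    )


def _baseline_means(config: SyntheticConfig) -> np.ndarray:
    """Per-taxon latent baselines, drawn once from their own stream."""
    rng = _rng(config, _STREAM_BASELINE)
    return rng.normal(0.0, config.baseline_log_sd, size=config.n_taxa)


def _effect_matrix(config: SyntheticConfig) -> np.ndarray:
    eff = np.zeros((config.n_taxa, config.n_groups))
    for taxon, group, log2_effect in config.effect_spec:
        eff[taxon, group] += log2_effect
    return eff


def _sample_latent(
    rng: np.random.Generator, n: int, n_taxa: int, blocks: Sequence[tuple[int, float]]
) -> np.ndarray:
    """n x n_taxa draws from MVN(0, C) with block compound-symmetric C."""
    z = rng.standard_normal((n, n_taxa))
    start = 0
    for size, rho in blocks:
        if rho != 0.0 and size > 1:
            block = np.full((size, size), rho)
            np.fill_diagonal(block, 1.0)
            try:
                chol = np.linalg.cholesky(block)
            except np.linalg.LinAlgError as exc:  # rho at the PSD boundary
                chol = _psd_factor(block)
                if chol is None:
                    raise ConfigError(
                        f"block (size={size}, rho={rho}) covariance not PSD"
                    ) from exc
            z[:, start : start + size] = z[:, start : start + size] @ chol.T
        start += size
    return z


def _psd_factor(block: np.ndarray) -> np.ndarray | None:
    vals, vecs = np.linalg.eigh(block)
    if vals.min() < -1e-8:
        return None
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def generate_counts(config: SyntheticConfig) -> CountTable:
    """Draw the genus-level count table for every sample in the design.

    Deterministic given ``config.seed``; sample IDs are ``<group>_s<j>``
    and taxon names ``g000 .. g<n_taxa-1>``.
    """
    rng = _rng(config, _STREAM_COUNTS)
    mu = _baseline_means(config)
    eff = _effect_matrix(config)
    taxa = [f"g{t:03d}" for t in range(config.n_taxa)]
    rows, sample_ids, labels = [], [], []
    for g, gname in enumerate(config.group_names):
        z = _sample_latent(rng, config.n_samples_per_group, config.n_taxa, config.block_spec[g])
        eta = mu[None, :] + np.log(2.0) * eff[:, g][None, :] + z
        # softmax per sample -> composition
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        p /= p.sum(axis=1, keepdims=True)
        for j in range(config.n_samples_per_group):
            rows.append(rng.multinomial(config.sequencing_depth, p[j]))
            sample_ids.append(f"{gname}_s{j}")
            labels.append(gname)
    counts = pd.DataFrame(np.array(rows, dtype=np.int64), index=sample_ids, columns=taxa)
    return CountTable(counts, pd.Series(labels, index=sample_ids, name="group"))


def clr_transform(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Centered log-ratio of a count matrix with a pseudocount for zeros."""
    x = counts.to_numpy(dtype=float) + pseudocount
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=counts.index, columns=counts.columns)


def generate_phenotypes(config: SyntheticConfig, counts: CountTable) -> OmicsBlock:
    """Continuous phenotypes linked (or not) to planted taxa.

    ``phenotype = group_shift[g] + slope * clr(linked taxon) + N(0, noise_sd)``.
    """
    if not config.phenotype_spec:
        raise ConfigError("config declares no phenotypes")
    rng = _rng(config, _STREAM_PHENOTYPES)
    clr = clr_transform(counts.counts)
    group_index = {name: g for g, name in enumerate(config.group_names)}
    cols = {}
    for spec in config.phenotype_spec:
        shifts = np.array([spec.group_shift[group_index[g]] for g in counts.groups])
        if spec.linked_taxon_index is not None:
            if spec.linked_taxon_index >= counts.n_taxa:
                raise ConfigError(
                    f"phenotype {spec.name!r}: linked taxon index out of range"
                )
            link = spec.slope * clr.iloc[:, spec.linked_taxon_index].to_numpy()
        else:
            link = 0.0
        noise = rng.normal(0.0, spec.noise_sd, size=counts.n_samples) if spec.noise_sd > 0 else 0.0
        cols[spec.name] = shifts + link + noise
    values = pd.DataFrame(cols, index=counts.counts.index)
    return OmicsBlock(values, tag="phenotype")


def generate_pathways(config: SyntheticConfig, counts: CountTable) -> OmicsBlock:
    """Pathway abundances as non-negative taxon mixtures with lognormal noise.

    Each pathway takes ``pathway_k`` distinct taxa with uniform(0.5, 1.5)
    weights on their relative abundances; multiplicative lognormal noise with
    log-sd ``pathway_noise_sd`` (no noise if 0).
    """
    rng = _rng(config, _STREAM_PATHWAYS)
    rel = counts.counts.to_numpy(dtype=float)
    rel = rel / rel.sum(axis=1, keepdims=True)
    cols = {}
    if config.pathway_spec is not None:
        mixes = [
            (name, np.fromiter(weights.keys(), dtype=int), np.fromiter(weights.values(), dtype=float))
            for name, weights in config.pathway_spec
        ]
    else:
        k = min(config.pathway_k, config.n_taxa)
        mixes = []
        for p in range(config.n_pathways):
            members = rng.choice(config.n_taxa, size=k, replace=False)
            weights = rng.uniform(0.5, 1.5, size=k)
            mixes.append((f"pwy{p:04d}", members, weights))
    for name, members, weights in mixes:
        values = rel[:, members] @ weights if len(members) else np.zeros(rel.shape[0])
        if config.pathway_noise_sd > 0:
            values = values * rng.lognormal(0.0, config.pathway_noise_sd, size=len(values))
        cols[name] = values
    block = OmicsBlock(pd.DataFrame(cols, index=counts.counts.index), tag="pathway")
    degenerate = [c for c in block.values.columns if block.values[c].nunique() <= 1]
    if degenerate:
        block.flags["degenerate"] = degenerate
    return block


def study_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The default three-arm hypertension study design.

    Control carries one large 12-genus correlation block; the hypertensive
    group the same genera fragmented into four 3-genus blocks; the treated
    group an intermediate two-block structure.  Four genera outside the
    blocks are planted as differential: one enriched under hypertension and
    rebalanced by treatment, one enriched and not restored, two suppressed
    and not restored.  Blood pressure and trabecular bone phenotypes are
    linked to planted taxa.
    """
    base = dict(
        n_groups=3,
        n_samples_per_group=8,
        n_taxa=200,
        sequencing_depth=20_000,
        group_names=("control", "hypertensive", "treated"),
        block_spec=[
            [(12, 0.7)],
            [(3, 0.7), (3, 0.7), (3, 0.7), (3, 0.7)],
            [(6, 0.7), (6, 0.7)],
        ],
        effect_spec=[
            (12, 1, 2.0),   # enriched under hypertension, rebalanced by treatment
            (12, 2, 0.3),
            (13, 1, 2.0),   # enriched, not restored
            (13, 2, 1.8),
            (14, 1, -2.0),  # suppressed, not restored
            (14, 2, -1.8),
            (15, 1, -2.0),
            (15, 2, -1.8),
        ],
        phenotype_spec=[
            PhenotypeSpec("blood_pressure", 12, 6.0, 5.0, (120.0, 160.0, 135.0)),
            PhenotypeSpec("BV_TV", 12, -0.01, 0.02, (0.35, 0.25, 0.28)),
            PhenotypeSpec("Tb_Th", 13, -0.003, 0.005, (0.09, 0.07, 0.08)),
            PhenotypeSpec("Tb_N", 14, 0.1, 0.2, (4.5, 3.5, 3.8)),
            PhenotypeSpec("Tb_Sp", None, 0.0, 0.05, (0.25, 0.35, 0.32)),
        ],
        seed=seed,
    )
    base.update(overrides)
    return SyntheticConfig(**base)
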