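"""Synthetic fixtures: CA reference chains, noise-controlled decoy
pools with planted conformational clusters, alignments with controlled
per-column depth, and template-hit tables around a planted domain
partition.

Every generator is a pure function of its arguments and a seed, and
each decoy pool ships a truth table (true TM/GDT against the
reference, planted conformation, noise level) so downstream ranking
and clustering behaviour can be scored against known ground truth.
The pools emulate the situation where one (possibly wrong)
conformation dominates a prediction pool while the correct fold sits
in a small minority cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .compare import FAST_POOL_PARAMS, ScoringParams, gdt_ts, tm_score
from .containers import (
    AA20,
    DomainSegmentation,
    Msa,
    SequenceRecord,
    StructureModel,
    TemplateHit,
)
from .errors import ArgumentError, GenerationError

__all__ = [
    "Conformation",
    "PlddtModel",
    "DecoyPoolSpec",
    "make_reference_chain",
    "make_decoys",
    "make_msa",
    "make_hit_table",
]

CA_DISTANCE = 3.8  # consecutive CA-CA distance, Å


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def make_reference_chain(
    length: int,
    style: str = "helix",
    rng_seed: int = 0,
    max_attempts: int = 200,
) -> StructureModel:
    """Idealised CA trace to serve as a synthetic native structure.

    ``helix`` uses ideal alpha-helix geometry (1.5 Å rise, 100° twist,
    radius tuned for a 3.8 Å CA-CA distance); ``random_walk`` is a
    self-avoiding 3.8 Å-step walk whose non-consecutive CAs stay at
    least 4 Å apart.
    """
    if length < 5:
        raise ArgumentError("length must be >= 5")
    rng = np.random.default_rng(rng_seed)
    if style == "helix":
        rise, twist = 1.5, np.deg2rad(100.0)
        radius = np.sqrt(CA_DISTANCE**2 - rise**2) / (2 * np.sin(twist / 2))
        i = np.arange(length)
        coords = np.column_stack(
            [radius * np.cos(i * twist), radius * np.sin(i * twist), rise * i]
        )
    elif style == "random_walk":
        coords = _self_avoiding_walk(length, rng, max_attempts)
    else:
        raise ArgumentError(f"unknown style {style!r}")
    return StructureModel(
        model_id=f"ref_{style}_{length}",
        residue_ids=np.arange(1, length + 1),
        ca_coords=coords,
        sequence=_random_sequence(length, rng),
        generator="other",
    )


def _self_avoiding_walk(
    length: int, rng: np.random.Generator, max_attempts: int, min_sep: float = 4.0
) -> np.ndarray:
    for _ in range(max_attempts):
        coords = [np.zeros(3), np.array([CA_DISTANCE, 0.0, 0.0])]
        ok = True
        for _ in range(length - 2):
            placed = False
            prev_dir = coords[-1] - coords[-2]
            prev_dir /= np.linalg.norm(prev_dir)
            for _ in range(60):
                # persistence keeps the walk extended enough to close rarely
                step = prev_dir + 0.9 * rng.standard_normal(3)
                step *= CA_DISTANCE / np.linalg.norm(step)
                cand = coords[-1] + step
                earlier = np.array(coords[:-1])
                if len(earlier) == 0 or np.min(
                    np.linalg.norm(earlier - cand, axis=1)
                ) >= min_sep:
                    coords.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.array(coords)
    raise GenerationError(
        f"could not build a self-avoiding walk of length {length} "
        f"in {max_attempts} attempts"
    )


@dataclass(frozen=True)
class Conformation:
    """A planted pool conformation: the reference hinged at its midpoint."""

    weight: float
    hinge_angle_deg: float = 0.0


@dataclass(frozen=True)
class PlddtModel:
    """Affine-plus-noise link between true quality and simulated plDDT.

    ``rho`` is the target Pearson correlation between the pool's true
    TM-scores and the simulated global plDDT; mean/sd set the plDDT
    scale (0-100).  ``rho = 0`` makes confidence pure noise, emulating
    predictors that cannot tell the wrong dominant conformation from
    the right minority one.
    """

    rho: float = 0.8
    mean: float = 80.0
    sd: float = 8.0


@dataclass(frozen=True)
class DecoyPoolSpec:
    n_models: int = 100
    sigma_grid: tuple[float, ...] = (1.0,)
    conformations: tuple[Conformation, ...] = (Conformation(weight=1.0),)
    plddt_model: PlddtModel = field(default_factory=PlddtModel)
    #: fraction of models tagged as AlphaFold3 output
    af3_fraction: float = 0.3
    rng_seed: int = 0
    #: scoring parameters used to record the truth table; the global
    #: seed suffices for same-length full-coverage decoys
    truth_params: ScoringParams = FAST_POOL_PARAMS
    score_gdt: bool = False

    def __post_init__(self) -> None:
        w = sum(c.weight for c in self.conformations)
        if abs(w - 1.0) > 1e-9:
            raise ArgumentError(f"conformation weights sum to {w}, expected 1")
        if any(s < 0 for s in self.sigma_grid) or not self.sigma_grid:
            raise ArgumentError("sigma_grid must be non-empty and non-negative")


def _hinge_transform(
    ref: StructureModel, angle_deg: float, rng: np.random.Generator
) -> np.ndarray:
    """Rotate the C-terminal half about a random axis through the
    midpoint CA; the axis is fixed per conformation (drawn once)."""
    coords = ref.ca_coords.copy()
    if angle_deg == 0.0:
        return coords
    mid = len(coords) // 2
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis)
    pivot = coords[mid]
    coords[mid + 1 :] = rot.apply(coords[mid + 1 :] - pivot) + pivot
    return coords


def make_decoys(
    ref: StructureModel, spec: DecoyPoolSpec
) -> tuple[list[StructureModel], pd.DataFrame]:
    """Sample a decoy pool around a reference chain.

    Each decoy picks a conformation by weight, adds isotropic Gaussian
    coordinate noise (sigma cycling through ``sigma_grid``), and is
    placed in a random rigid frame.  The truth table records the
    planted conformation, sigma, the true TM (and optionally GDT-TS)
    against the reference, the simulated global plDDT and the
    generator tag.
    """
    rng = np.random.default_rng(spec.rng_seed)
    conf_coords = [
        _hinge_transform(ref, c.hinge_angle_deg, rng) for c in spec.conformations
    ]
    weights = np.array([c.weight for c in spec.conformations])
    conf_idx = rng.choice(len(weights), size=spec.n_models, p=weights)
    n_af3 = int(round(spec.af3_fraction * spec.n_models))
    generators = np.array(["af3"] * n_af3 + ["af2"] * (spec.n_models - n_af3))
    rng.shuffle(generators)

    models: list[StructureModel] = []
    rows = []
    for i in range(spec.n_models):
        sigma = spec.sigma_grid[i % len(spec.sigma_grid)]
        coords = conf_coords[conf_idx[i]] + sigma * rng.standard_normal((len(ref), 3))
        frame = Rotation.random(random_state=rng)
        coords = frame.apply(coords) + rng.uniform(-50, 50, size=3)
        model = StructureModel(
            model_id=f"decoy_{i:04d}",
            residue_ids=ref.residue_ids.copy(),
            ca_coords=coords,
            sequence=ref.sequence,
            generator=str(generators[i]),
        )
        true_tm = tm_score(ref, model, spec.truth_params)
        true_gdt = gdt_ts(ref, model, spec.truth_params) if spec.score_gdt else np.nan
        models.append(model)
        rows.append((model.model_id, int(conf_idx[i]), sigma, true_tm, true_gdt,
                     str(generators[i])))
    truth = pd.DataFrame(
        rows, columns=["model_id", "conformation", "sigma", "true_tm", "true_gdt",
                       "generator"],
    )
    # simulated confidence: correlate with true quality at the target rho
    tm = truth["true_tm"].to_numpy()
    z = (tm - tm.mean()) / tm.std() if tm.std() > 0 else np.zeros_like(tm)
    rho = spec.plddt_model.rho
    noise = rng.standard_normal(spec.n_models)
    plddt = spec.plddt_model.mean + spec.plddt_model.sd * (
        rho * z + np.sqrt(max(0.0, 1 - rho**2)) * noise
    )
    plddt = np.clip(plddt, 0, 100)
    truth["plddt_global"] = plddt
    for model, g in zip(models, plddt):
        model.plddt = np.clip(
            g + 2.0 * rng.standard_normal(len(ref)), 0, 100
        )
        model.ranking_score = float(g) / 100.0
    return models, truth


def make_msa(
    length: int,
    n_rows: int,
    coverage_profile: Sequence[float] | float = 1.0,
    substitution_rate: float = 0.2,
    rng_seed: int = 0,
) -> Msa:
    """Alignment with controlled per-column depth.

    Row ``i`` covers column ``c`` with probability
    ``coverage_profile[c]`` (independent Bernoulli draws); covered
    positions mutate away from the query at ``substitution_rate``.
    A scalar profile applies uniformly, so a step profile reproduces
    the shallow-tail pathology of real alignments.
    """
    rng = np.random.default_rng(rng_seed)
    profile = np.broadcast_to(
        np.asarray(coverage_profile, dtype=float), (length,)
    ).copy()
    if profile.min() < 0 or profile.max() > 1:
        raise ArgumentError("coverage probabilities must lie in [0, 1]")
    query_seq = _random_sequence(length, rng)
    aa = np.array(list(AA20))
    rows = []
    for i in range(n_rows):
        covered = rng.random(length) < profile
        mutate = covered & (rng.random(length) < substitution_rate)
        chars = np.full(length, "-", dtype="<U1")
        chars[covered] = np.array(list(query_seq))[covered]
        if mutate.any():
            # draw a uniformly random *different* residue at mutated sites
            offsets = rng.integers(1, len(aa), size=int(mutate.sum()))
            orig = np.array([AA20.index(c) for c in np.array(list(query_seq))[mutate]])
            chars[mutate] = aa[(orig + offsets) % len(aa)]
        rows.append(SequenceRecord(identifier=f"S{i + 1:06d}",
                                   residues="".join(chars)))
    msa = Msa(
        query=SequenceRecord(identifier="query", residues=query_seq),
        rows=rows,
        insertions=[{} for _ in rows],
    )
    msa.validate()
    return msa


def make_hit_table(
    segmentation: DomainSegmentation,
    jitter: int = 0,
    decoy_hits: int = 0,
    rng_seed: int = 0,
    edge_margin: int = 10,
) -> list[TemplateHit]:
    """Template hits around a planted domain partition.

    Each planted domain emits one significant hit shrunk by
    ``edge_margin`` (plus uniform jitter) at internal boundaries, so
    that midpoint splitting of the short unaligned gaps between hits
    recovers the planted boundaries (exactly at zero jitter, within
    ``jitter`` residues otherwise).  ``decoy_hits`` extra hits each
    violate one significance filter and must vanish under filtering.
    """
    segmentation.validate()
    rng = np.random.default_rng(rng_seed)
    hits: list[TemplateHit] = []
    n_dom = len(segmentation.domains)
    for k, (start, end) in enumerate(segmentation.domains):
        m_left = edge_margin + int(rng.integers(-jitter, jitter + 1)) if k > 0 else 0
        m_right = (
            edge_margin + int(rng.integers(-jitter, jitter + 1)) if k < n_dom - 1 else 0
        )
        hit_start = start + max(0, m_left)
        hit_end = end - max(0, m_right)
        aligned = hit_end - hit_start + 1
        if aligned <= 40:
            raise GenerationError(
                f"domain [{start}, {end}] too short to emit a significant hit "
                f"after a {edge_margin}-residue edge margin"
            )
        hits.append(
            TemplateHit(
                template_id=f"tpl_dom{k + 1}",
                target_start=hit_start,
                target_end=hit_end,
                evalue=float(10.0 ** rng.uniform(-30, -3)),
                template_length=aligned,
                coverage=1.0,
            )
        )
    failure_modes = ["evalue", "length", "coverage"]
    for k in range(decoy_hits):
        start, end = segmentation.domains[int(rng.integers(n_dom))]
        mode = failure_modes[k % len(failure_modes)]
        d_start = int(rng.integers(start, max(start + 1, end - 45)))
        d_end = min(end, d_start + 60)
        evalue, coverage = 1e-5, 0.9
        if mode == "evalue":
            evalue = float(rng.uniform(1.5, 50.0))
        elif mode == "length":
            d_end = min(end, d_start + int(rng.integers(5, 41)) - 1)
        else:
            coverage = float(rng.uniform(0.05, 0.5))
        hits.append(
            TemplateHit(
                template_id=f"decoy_{k + 1}_{mode}",
                target_start=d_start,
                target_end=d_end,
                evalue=evalue,
                template_length=d_end - d_start + 1,
                coverage=coverage,
            )
        )
    return hits
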