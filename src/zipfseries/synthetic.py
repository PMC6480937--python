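"""Synthetic communities and proportional-growth process histories.

Two generative routes produce test data for every other module with no
external input:

* **Family route** — draw abundances directly from a continuum member
  (beta, lam) and discretize to integer counts.
* **Process route** — accumulate a proportional-process intensity m(t)
  over a horizon tau, giving the growth total r = ∫₀^τ m(t) dt and the
  abundance n = e^r (initial abundance fixed at 1, so r = log n exactly).

The supported intensity forms are exactly integrable (constant,
piecewise-constant) or i.i.d. per-step increments; there is no quadrature
inside the generator, so provenance is sharp.  The shipped m(t) families
are illustrations of proportional process, not claims about any
particular ecological mechanism.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .family import AbundanceDistribution, solve_lambda
from .sampling import SamplerConfig, sample_abundance, sample_logseries

__all__ = [
    "ProcessModel",
    "SyntheticCommunity",
    "run_process",
    "make_community",
    "make_fixture_suite",
]

_DISCRETIZATIONS = ("round_half_up", "ceiling")


@dataclass(frozen=True)
class ProcessModel:
    """Proportional-process history: intensity spec m(t) on [0, tau].

    ``m_spec`` is one of
      ("constant", c)                      — m(t) = c
      ("piecewise", ((m1, dt1), (m2, dt2), ...)) — value/duration segments;
          durations must sum to tau
      ("iid", dist_name, params)           — per-unit-step i.i.d. increments;
          tau must be a positive integer number of steps; dist_name in
          {"normal": (mu, sigma), "uniform": (lo, hi), "exponential": (rate,)}

    The initial abundance is fixed at 1, so the accumulated total r equals
    log n for the grown abundance n = e^r.
    """

    tau: float
    m_spec: tuple
    n0: float = 1.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        kind = self.m_spec[0]
        if kind == "constant":
            pass
        elif kind == "piecewise":
            durs = sum(dt for _, dt in self.m_spec[1])
            if any(dt <= 0 for _, dt in self.m_spec[1]):
                raise ValueError("piecewise segment durations must be > 0")
            if not math.isclose(durs, self.tau, rel_tol=1e-12):
                raise ValueError(
                    f"piecewise durations sum to {durs}, expected tau={self.tau}"
                )
        elif kind == "iid":
            if self.m_spec[1] not in ("normal", "uniform", "exponential"):
                raise ValueError(f"unsupported increment family {self.m_spec[1]!r}")
            if self.tau != int(self.tau):
                raise ValueError("iid increments need an integer number of steps")
        else:
            raise ValueError(f"unsupported m_spec kind {kind!r}")


def run_process(model: ProcessModel, size: int, seed: int) -> np.ndarray:
    """Integrate m(t) over [0, tau] for ``size`` replicates.

    Returns an array of shape (size, 2) with columns (r, n = e^r).
    Constant and piecewise intensities integrate exactly (r = c*tau and
    the duration-weighted sum); i.i.d. increments sum tau unit steps.
    """
    if size < 1:
        raise ValueError(f"size must be >= 1, got {size}")
    kind = model.m_spec[0]
    if kind == "constant":
        r = np.full(size, model.m_spec[1] * model.tau, dtype=float)
    elif kind == "piecewise":
        total = sum(m * dt for m, dt in model.m_spec[1])
        r = np.full(size, total, dtype=float)
    else:  # iid
        rng = np.random.default_rng(seed)
        steps = int(model.tau)
        name, params = model.m_spec[1], model.m_spec[2]
        if name == "normal":
            incr = rng.normal(params[0], params[1], size=(size, steps))
        elif name == "uniform":
            incr = rng.uniform(params[0], params[1], size=(size, steps))
        else:
            incr = rng.exponential(1.0 / params[0], size=(size, steps))
        r = incr.sum(axis=1)
    return np.column_stack([r, np.exp(r)])


@dataclass(frozen=True)
class SyntheticCommunity:
    """Integer abundances plus the provenance needed to regenerate them."""

    abundances: np.ndarray
    generator_tag: dict

    def __post_init__(self) -> None:
        if np.any(self.abundances < 1):
            raise ValueError("all abundances must be >= 1")

    def __len__(self) -> int:
        return int(self.abundances.size)


def _discretize(values: np.ndarray, rule: str) -> np.ndarray:
    if rule == "round_half_up":
        out = np.floor(values + 0.5)
    elif rule == "ceiling":
        out = np.ceil(values)
    else:
        raise ValueError(
            f"discretization must be one of {_DISCRETIZATIONS}, got {rule!r}"
        )
    return np.maximum(out, 1.0).astype(np.int64)


def make_community(
    beta: float,
    n_species: int,
    seed: int,
    lam: Optional[float] = None,
    mean: Optional[float] = None,
    discretization: str = "round_half_up",
) -> SyntheticCommunity:
    """Draw a community of integer abundances from a continuum member.

    Exactly one of ``lam`` or ``mean`` must be given; a mean is converted
    to lam with :func:`zipfseries.family.solve_lambda`.  Continuous draws
    are discretized by the stated rule (floored at 1); the rule is part of
    the recorded provenance.
    """
    if n_species < 1:
        raise ValueError(f"n_species must be >= 1, got {n_species}")
    if (lam is None) == (mean is None):
        raise ValueError("give exactly one of lam or mean")
    lam_val = float(lam) if lam is not None else solve_lambda(beta, mean)
    dist = AbundanceDistribution(beta, lam_val)
    draws = sample_abundance(dist, n_species, SamplerConfig(seed=seed))
    counts = _discretize(draws, discretization)
    tag = {
        "generator": "family",
        "beta": beta,
        "lam": lam_val,
        "mean_target": mean,
        "n_species": n_species,
        "seed": seed,
        "discretization": discretization,
        "version": __version__,
    }
    return SyntheticCommunity(abundances=counts, generator_tag=tag)


def _logseries_community(p: float, n_species: int, seed: int) -> SyntheticCommunity:
    counts = sample_logseries(p, n_species, seed)
    tag = {
        "generator": "discrete_logseries",
        "p": p,
        "n_species": n_species,
        "seed": seed,
        "discretization": "exact_discrete",
        "version": __version__,
    }
    return SyntheticCommunity(abundances=counts.astype(np.int64), generator_tag=tag)


def write_community_tsv(community: SyntheticCommunity, path) -> None:
    """Write a community as two-column TSV (species label, count)."""
    path = Path(path)
    lines = ["species\tabundance"]
    width = len(str(len(community)))
    for i, n in enumerate(community.abundances, start=1):
        lines.append(f"sp{i:0{width}d}\t{int(n)}")
    path.write_text("\n".join(lines) + "\n")


def make_fixture_suite(out_dir) -> dict:
    """Write a fixed set of seeded communities plus a provenance manifest.

    Three family members (Zipf beta=0 lam=1; log series p=0.8; the
    intermediate beta=0.5 lam=1) at S in {100, 10000} species each.  The
    log-series fixtures are exact discrete draws; the others are
    continuous draws discretized by round_half_up.  Regenerating with the
    same seeds reproduces the files byte-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    recipes = []
    for s_count, seed in ((100, 101), (10_000, 102)):
        recipes.append(
            (f"zipf_S{s_count}.tsv", make_community(0.0, s_count, seed, lam=1.0))
        )
    for s_count, seed in ((100, 201), (10_000, 202)):
        recipes.append(
            (f"logseries_S{s_count}.tsv", _logseries_community(0.8, s_count, seed))
        )
    for s_count, seed in ((100, 301), (10_000, 302)):
        recipes.append(
            (
                f"intermediate_S{s_count}.tsv",
                make_community(0.5, s_count, seed, lam=1.0),
            )
        )
    manifest = {"version": __version__, "files": {}}
    for fname, community in recipes:
        write_community_tsv(community, out / fname)
        manifest["files"][fname] = community.generator_tag
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
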