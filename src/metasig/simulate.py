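"""Synthetic inputs with the statistical structure each stage assumes.

One global seed drives independent per-stage child streams through
``numpy.random.SeedSequence(seed, spawn_key=(stage_index,))``, so any
stage can be regenerated on its own and identical configurations yield
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .diagmeta import Diagnostic2x2
from .ingest import DOWN, UP, StudySignature
from .survival import SurvivalCohort

__all__ = [
    "SimConfig",
    "simulate_study_lists",
    "simulate_diagnostic_tables",
    "simulate_expression",
    "simulate_survival",
    "write_all",
]

# stage indices of the seed-splitting scheme
_STAGE_RRA, _STAGE_DIAG, _STAGE_EXPR, _STAGE_SURV = 0, 1, 2, 3

# platform sizes of the 14 emulated profiling studies (range 85..2064)
DEFAULT_PLATFORM_SIZES = (235, 314, 462, 515, 498, 365, 739, 1105, 1105, 2064, 739, 754, 1757, 85)


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


@dataclass(frozen=True)
class DiagnosticSim:
    """Bivariate generator defaults mirror a five-study qRT-PCR panel
    (case/control sizes 20/8, 28/28, 28/28, 52/18, 22/22); scalar sizes
    are recycled across studies."""

    n_studies: int = 5
    mu_se: float = logit(0.84)
    mu_sp: float = logit(0.83)
    tau2_se: float = 0.2
    tau2_sp: float = 0.2
    tau_cov: float = -0.1
    n_cases: int | tuple[int, ...] = (20, 28, 28, 52, 22)
    n_controls: int | tuple[int, ...] = (8, 28, 28, 18, 22)

    def __post_init__(self) -> None:
        if self.tau2_se < 0 or self.tau2_sp < 0:
            raise ValueError("variances must be non-negative")
        if self.tau_cov**2 > self.tau2_se * self.tau2_sp + 1e-12:
            raise ValueError("between-study covariance not positive semi-definite")

    def arm_sizes(self) -> tuple[tuple[int, ...], tuple[int, ...]]:
        def _expand(v) -> tuple[int, ...]:
            if isinstance(v, int):
                return (v,) * self.n_studies
            if len(v) == self.n_studies:
                return tuple(int(x) for x in v)
            # recycle the pattern to the requested number of studies
            return tuple(int(v[i % len(v)]) for i in range(self.n_studies))

        return _expand(self.n_cases), _expand(self.n_controls)


@dataclass(frozen=True)
class ExpressionSim:
    n_samples: int = 60
    n_background_genes: int = 300
    mirna_names: tuple[str, ...] = ("hsa-miR-200a-3p", "hsa-miR-200c-3p")
    mirna_corr: float = 0.5
    planted_genes: tuple[str, ...] = (
        "CDH1", "DSC2", "F11R", "CDH2", "ITGA5", "MMP2", "ERBB3", "COL5A2", "COL1A2",
    )
    planted_rho: float = 0.8

    def __post_init__(self) -> None:
        if abs(self.planted_rho) > 1 or abs(self.mirna_corr) > 1:
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass(frozen=True)
class SurvivalSim:
    n_patients: int = 458
    true_betas: tuple[float, ...] = (math.log(2.0), 0.0)
    panel_names: tuple[str, ...] = ("hsa-miR-200a-3p", "hsa-miR-200c-3p")
    baseline_hazard: float = 0.1
    censoring_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if len(self.true_betas) != len(self.panel_names):
            raise ValueError("true_betas/panel_names length mismatch")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of all four generator stages under one seed."""

    seed: int = 42
    n_studies: int = 14
    platform_sizes: tuple[int, ...] = DEFAULT_PLATFORM_SIZES
    n_planted_up: int = 4
    n_planted_down: int = 2
    planted_strength: float = 0.9
    planted_top_fraction: float = 0.25
    list_length_range: tuple[int, int] = (10, 77)
    n_background: int = 150
    diagnostic: DiagnosticSim = field(default_factory=DiagnosticSim)
    expression: ExpressionSim = field(default_factory=ExpressionSim)
    survival: SurvivalSim = field(default_factory=SurvivalSim)

    def __post_init__(self) -> None:
        if not 0.0 <= self.planted_strength <= 1.0:
            raise ValueError("planted_strength must lie in [0, 1]")
        if len(self.platform_sizes) != self.n_studies:
            raise ValueError("platform_sizes length must equal n_studies")
        lo, hi = self.list_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid list_length_range")
        if max(self.n_planted_up, self.n_planted_down) > lo:
            raise ValueError("planted miRNAs exceed the minimum list length")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# stage generators
# ---------------------------------------------------------------------------


def _mirna_names(prefix: str, n: int) -> list[str]:
    return [f"hsa-miR-{prefix}{i:03d}-5p" for i in range(1, n + 1)]


def simulate_study_lists(config: SimConfig) -> list[StudySignature]:
    """Study signatures in both directions with planted consistent miRNAs.

    A planted miRNA enters each study's correct-direction list with
    probability ``planted_strength`` at a position inside the top
    ``planted_top_fraction`` of the list; the remaining slots are filled
    with background miRNAs drawn uniformly per study.
    """
    rng = _rng(config.seed, _STAGE_RRA)
    planted = {
        UP: _mirna_names("up", config.n_planted_up),
        DOWN: _mirna_names("dn", config.n_planted_down),
    }
    background = {
        UP: _mirna_names("bgu", config.n_background),
        DOWN: _mirna_names("bgd", config.n_background),
    }
    lo, hi = config.list_length_range
    signatures: list[StudySignature] = []
    for s in range(config.n_studies):
        study_id = f"study{s + 1:02d}"
        platform = int(config.platform_sizes[s])
        for direction in (UP, DOWN):
            length = int(rng.integers(lo, hi + 1))
            length = min(length, platform)
            included = [m for m in planted[direction] if rng.random() < config.planted_strength]
            top = max(len(included), int(math.ceil(length * config.planted_top_fraction)))
            positions = rng.choice(top, size=len(included), replace=False)
            slots: list[str | None] = [None] * length
            for m, pos in zip(included, sorted(positions)):
                slots[int(pos)] = m
            n_bg = length - len(included)
            bg = rng.choice(background[direction], size=n_bg, replace=False)
            it = iter(bg)
            members = tuple(m if m is not None else str(next(it)) for m in slots)
            signatures.append(
                StudySignature(
                    study_id=study_id,
                    platform_size=platform,
                    direction=direction,
                    members=members,
                )
            )
    return signatures


def simulate_diagnostic_tables(config: SimConfig) -> list[Diagnostic2x2]:
    """2x2 tables drawn from the bivariate random-effects model."""
    d = config.diagnostic
    rng = _rng(config.seed, _STAGE_DIAG)
    cov = np.array([[d.tau2_se, d.tau_cov], [d.tau_cov, d.tau2_sp]])
    mean = np.array([d.mu_se, d.mu_sp])
    cases, controls = d.arm_sizes()
    tables = []
    for i in range(d.n_studies):
        ls, lp = rng.multivariate_normal(mean, cov, method="svd")
        se, sp = expit(ls), expit(lp)
        tp = int(rng.binomial(cases[i], se))
        tn = int(rng.binomial(controls[i], sp))
        tables.append(
            Diagnostic2x2(
                study_id=f"diag{i + 1:02d}",
                tp=tp, fn=cases[i] - tp, tn=tn, fp=controls[i] - tn,
            )
        )
    return tables


def simulate_expression(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(miRNA x samples, gene x samples) matrices with planted correlations.

    The panel miRNAs are pairwise correlated at ``mirna_corr``; each
    planted gene follows the standardized panel average with loading
    ``planted_rho`` (so its correlation with each single miRNA is
    ``planted_rho * sqrt((1 + mirna_corr) / 2)`` for a two-miRNA panel);
    background genes are independent noise.
    """
    e = config.expression
    if e.n_samples < 3:
        raise ValueError("need at least 3 samples")
    rng = _rng(config.seed, _STAGE_EXPR)
    n = e.n_samples
    samples = [f"CELL{i + 1:03d}" for i in range(n)]

    def _std(v: np.ndarray) -> np.ndarray:
        return (v - v.mean()) / v.std()

    base = _std(rng.standard_normal(n))
    mirnas = {}
    c = e.mirna_corr
    for k, name in enumerate(e.mirna_names):
        if k == 0:
            mirnas[name] = base
        else:
            noise = _std(rng.standard_normal(n))
            noise = _std(noise - noise @ base / n * base)  # exact orthogonalization
            mirnas[name] = c * base + math.sqrt(1 - c * c) * noise
    M = np.vstack([mirnas[name] for name in e.mirna_names])
    shared = _std(M.mean(axis=0))

    genes: dict[str, np.ndarray] = {}
    rho = e.planted_rho
    for g in e.planted_genes:
        if abs(rho) == 1.0:
            genes[g] = rho * shared
        else:
            noise = _std(rng.standard_normal(n))
            noise = _std(noise - noise @ shared / n * shared)
            genes[g] = rho * shared + math.sqrt(1 - rho * rho) * noise
    for i in range(e.n_background_genes):
        genes[f"BGGENE{i + 1:04d}"] = rng.standard_normal(n)

    mirna_df = pd.DataFrame(M, index=list(e.mirna_names), columns=samples)
    gene_df = pd.DataFrame(np.vstack(list(genes.values())), index=list(genes), columns=samples)
    return mirna_df, gene_df


def simulate_survival(config: SimConfig) -> SurvivalCohort:
    """Proportional-hazards cohort with uniform independent censoring.

    Event times are exponential with hazard ``h0 * exp(beta . x)``;
    censoring times are Uniform(0, c) with ``c`` chosen by bisection so
    the realized expected censoring fraction matches the target.
    """
    s = config.survival
    rng = _rng(config.seed, _STAGE_SURV)
    n = s.n_patients
    X = rng.standard_normal((n, len(s.true_betas)))
    betas = np.asarray(s.true_betas)
    rate = s.baseline_hazard * np.exp(X @ betas)
    t_event = rng.exponential(1.0 / rate)
    frac = s.censoring_fraction
    if frac >= 1.0:
        time = t_event / 2.0
        event = np.zeros(n, dtype=int)
    elif frac <= 0.0:
        time = t_event
        event = np.ones(n, dtype=int)
    else:
        u = rng.uniform(0.0, 1.0, n)

        def expected_censored(c: float) -> float:
            return float(np.mean(np.minimum(t_event / c, 1.0)))

        lo, hi = 1e-9, float(t_event.max()) * 4
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if expected_censored(mid) > frac:
                lo = mid
            else:
                hi = mid
        c = 0.5 * (lo + hi)
        t_cens = u * c
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    time = np.maximum(time, 1e-9)
    return SurvivalCohort(
        patient_id=np.array([f"PT{i + 1:04d}" for i in range(n)]),
        time=time,
        event=event,
        panel=pd.DataFrame(X, columns=list(s.panel_names)),
    )


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------


def write_study_lists(config: SimConfig, outdir: Path) -> list[Path]:
    signatures = simulate_study_lists(config)
    rows = []
    for sig in signatures:
        for rank, m in enumerate(sig.members, start=1):
            rows.append((sig.study_id, sig.direction, m, rank))
    sig_path = outdir / "signatures.tsv"
    pd.DataFrame(rows, columns=["study_id", "direction", "mirna", "rank_or_effect"]).to_csv(
        sig_path, sep="\t", index=False
    )
    meta_rows = []
    seen = set()
    for sig in signatures:
        if sig.study_id not in seen:
            seen.add(sig.study_id)
            meta_rows.append((sig.study_id, sig.platform_size, 30, 15))
    meta_path = outdir / "study_metadata.tsv"
    pd.DataFrame(meta_rows, columns=["study_id", "platform_size", "n_cases", "n_controls"]).to_csv(
        meta_path, sep="\t", index=False
    )
    return [sig_path, meta_path]


def write_diagnostic_tables(config: SimConfig, outdir: Path) -> list[Path]:
    tables = simulate_diagnostic_tables(config)
    path = outdir / "diagnostic_tables.tsv"
    pd.DataFrame(
        [(t.study_id, t.tp, t.fp, t.fn, t.tn) for t in tables],
        columns=["study_id", "tp", "fp", "fn", "tn"],
    ).to_csv(path, sep="\t", index=False)
    return [path]


def write_expression(config: SimConfig, outdir: Path) -> list[Path]:
    mirna_df, gene_df = simulate_expression(config)
    p1 = outdir / "mirna_expression.tsv"
    p2 = outdir / "gene_expression.tsv"
    mirna_df.index.name = "mirna"
    gene_df.index.name = "gene"
    mirna_df.to_csv(p1, sep="\t", float_format="%.10g")
    gene_df.to_csv(p2, sep="\t", float_format="%.10g")
    # small target/pathway files so the enrichment stage runs locally
    e = config.expression
    planted = list(e.planted_genes)
    background = [f"BGGENE{i + 1:04d}" for i in range(e.n_background_genes)]
    p3 = outdir / "targets.tsv"
    rows = [(m, g) for m in e.mirna_names for g in planted]
    pd.DataFrame(rows, columns=["mirna", "gene"]).to_csv(p3, sep="\t", index=False)
    p4 = outdir / "pathways.gmt"
    lines = [
        "\t".join(["PATH_ADHESION", "planted adhesion-like set"] + planted + background[:5]),
        "\t".join(["PATH_OTHER1", "background set 1"] + background[5:45]),
        "\t".join(["PATH_OTHER2", "background set 2"] + background[45:105]),
    ]
    p4.write_text("\n".join(lines) + "\n")
    return [p1, p2, p3, p4]


def write_survival(config: SimConfig, outdir: Path) -> list[Path]:
    cohort = simulate_survival(config)
    path = outdir / "survival_cohort.tsv"
    cohort.to_tsv(path)
    return [path]


_STAGE_WRITERS = {
    "rra": write_study_lists,
    "diag": write_diagnostic_tables,
    "expr": write_expression,
    "surv": write_survival,
}


def write_all(config: SimConfig, outdir: str | Path, stage: str = "all") -> dict:
    """Write the requested stage(s) plus a manifest recording the config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(_STAGE_WRITERS) if stage == "all" else [stage]
    unknown = set(stages) - set(_STAGE_WRITERS)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    written: list[str] = []
    for st in stages:
        written += [str(p.name) for p in _STAGE_WRITERS[st](config, outdir)]
    manifest = {"config": config.to_dict(), "stages": stages, "files": written}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=float) + "\n"
    )
    return manifest
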