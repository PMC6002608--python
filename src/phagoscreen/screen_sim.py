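"""Synthetic-data generators for every stage of the screen.

The screen generator emulates the experiment end-to-end: a pooled
lentiviral library with log-normal representation skew infects cells at
low multiplicity (single integration), knockouts of essential genes drop
out before sorting, each cell is sorted into a phagocytosis-and-
acidification-positive (PhagoLate) or negative (PhagoNeg) gate with a
probability that depends on which gene was knocked out, and reads per
guide are drawn negative-binomially around the sorted-cell shares to
capture PCR/sequencing overdispersion.

Also provided: two-channel flow-cytometry event mixtures (bead-uptake dye
vs acidification dye) and BCECF ratio-vs-pH calibration tables, so the
gating and pH modules are testable without instrument data.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .library_index import LibraryIndex, default_library
from .read_counting import CassetteSpec, CountMatrix, sample_meta_from_ids

__all__ = [
    "ScreenSimConfig",
    "GroundTruth",
    "CassetteSpec",
    "SimulationError",
    "simulate_screen",
    "emit_fastq",
    "simulate_flow_events",
    "DEFAULT_CLUSTER_PARAMS",
    "bcecf_ratio",
    "simulate_bcecf",
]


class SimulationError(ValueError):
    """Raised when a simulation configuration is infeasible."""


@dataclasses.dataclass
class ScreenSimConfig:
    """Parameters of the synthetic screen.

    Defaults follow the screen design: infection at MOI 0.2-0.3 (0.25
    here), 1000x coverage, three replicates, and at least 3 million cells
    sorted per replicate and population. ``effect_map`` multiplies the
    baseline PhagoLate probability per knocked-out gene; a multiplier
    below 1 depletes that gene's guides from the PhagoLate gate.
    """

    index: LibraryIndex | None = None
    moi: float = 0.25
    coverage: int = 1000
    n_replicates: int = 3
    sort_depth: int = 3_000_000
    baseline_phago_prob: float = 0.4
    effect_map: Mapping[str, float] = dataclasses.field(default_factory=dict)
    editing_efficiency: float = 0.8
    essential_dropout: float = 0.2
    expansion: float = 10.0
    pcr_dispersion: float = 0.05
    read_depth: int = 500
    library_skew_sigma: float = 0.3
    include_initial: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.index is None:
            self.index = default_library(self.seed)
        for name in ("baseline_phago_prob", "editing_efficiency", "essential_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        if self.moi <= 0:
            raise SimulationError(f"moi must be > 0, got {self.moi}")
        for name in ("coverage", "n_replicates", "sort_depth", "read_depth"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be a positive integer")
        if self.pcr_dispersion < 0 or self.library_skew_sigma < 0:
            raise SimulationError("dispersion parameters must be non-negative")
        if self.expansion < 1:
            raise SimulationError("expansion must be >= 1")
        for gene, mult in self.effect_map.items():
            if mult < 0:
                raise SimulationError(f"effect multiplier for {gene} must be >= 0")
            if mult * self.baseline_phago_prob > 1.0:
                raise SimulationError(
                    f"effect multiplier {mult} for {gene} drives the PhagoLate "
                    f"probability above 1"
                )


@dataclasses.dataclass
class GroundTruth:
    """What the generator planted, for scoring recovery downstream."""

    effect_multipliers: dict[str, float]  # per gene; 1.0 = no effect
    hit_genes: list[str]  # genes with multiplier != 1
    expected_share: pd.DataFrame  # per-sgRNA expected read share per population

    def to_json(self, path: str | Path) -> None:
        obj = {
            "effect_multipliers": self.effect_multipliers,
            "hit_genes": self.hit_genes,
            "expected_share": self.expected_share.to_dict("index"),
        }
        Path(path).write_text(json.dumps(obj, indent=1))


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with Var = mu + dispersion * mu^2 (gamma-Poisson)."""
    mean = np.clip(mean, 1e-12, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def simulate_screen(config: ScreenSimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Simulate sorted-population sgRNA counts for the configured screen.

    Generative chain per replicate: multinomial infection of
    ``coverage x n_guides`` cells over the skewed library; editing with
    probability ``editing_efficiency``; essential-gene knockouts survive to
    the sort with probability ``essential_dropout``; each surviving cell is
    PhagoLate with probability ``baseline_phago_prob x multiplier(gene)``
    if edited (baseline if not), PhagoNeg otherwise; each gate is
    multinomially subsampled to ``sort_depth`` cells; reads per guide are
    negative-binomial around cell-share x total read budget.
    Deterministic for a fixed config (seed included).
    """
    index = config.index
    assert index is not None
    rng = np.random.default_rng(config.seed)
    n = len(index)
    genes = np.array([r.gene for r in index.records])
    is_essential = np.array([r.category == "EssentialControl" for r in index.records])
    mult = np.array([config.effect_map.get(g, 1.0) for g in genes])

    # library representation skew: one log-normal draw per guide, shared
    # across replicates (a property of the cloned library, not the infection)
    skew = rng.lognormal(mean=0.0, sigma=config.library_skew_sigma, size=n)
    p_library = skew / skew.sum()

    n_cells = config.coverage * n
    p_base = config.baseline_phago_prob
    eff = config.editing_efficiency
    p_late_edited = p_base * mult

    columns: dict[str, np.ndarray] = {}
    total_reads = config.read_depth * n
    for rep in range(1, config.n_replicates + 1):
        cells = rng.multinomial(n_cells, p_library)
        edited = rng.binomial(cells, eff)
        unedited = cells - edited
        # essential knockouts are lost before the sort; unedited cells are not
        edited = np.where(is_essential, rng.binomial(edited, config.essential_dropout), edited)
        # clonal outgrowth between selection and sort preserves founder skew
        edited = np.floor(edited * config.expansion).astype(np.int64)
        unedited = np.floor(unedited * config.expansion).astype(np.int64)
        late = rng.binomial(edited, p_late_edited) + rng.binomial(unedited, p_base)
        neg = (edited + unedited) - late
        for pop, cell_counts in (("PhagoLate", late), ("PhagoNeg", neg)):
            n_gate = int(cell_counts.sum())
            if config.sort_depth > n_gate:
                raise SimulationError(
                    f"sort_depth {config.sort_depth} exceeds the {n_gate} simulated "
                    f"cells in the {pop} gate of replicate {rep}"
                )
            sorted_cells = rng.multinomial(config.sort_depth, cell_counts / n_gate)
            share = sorted_cells / config.sort_depth
            columns[f"rep{rep}_{pop}"] = _nb_counts(
                rng, share * total_reads, config.pcr_dispersion
            )
        if config.include_initial:
            columns[f"rep{rep}_Initial"] = _nb_counts(
                rng, (cells / cells.sum()) * total_reads, config.pcr_dispersion
            )

    counts = pd.DataFrame(columns, index=pd.Index(index.sgrna_ids, name="sgrna_id"))
    matrix = CountMatrix(counts=counts, sample_meta=sample_meta_from_ids(list(columns)))

    # analytic expected read share per population under the generative chain
    w_unedited = (1.0 - eff) * np.ones(n)
    w_edited = np.where(is_essential, eff * config.essential_dropout, eff)
    exp_late = p_library * (w_edited * p_late_edited + w_unedited * p_base)
    exp_neg = p_library * (
        w_edited * (1.0 - p_late_edited) + w_unedited * (1.0 - p_base)
    )
    expected = pd.DataFrame(
        {
            "PhagoLate": exp_late / exp_late.sum(),
            "PhagoNeg": exp_neg / exp_neg.sum(),
        },
        index=pd.Index(index.sgrna_ids, name="sgrna_id"),
    )
    truth = GroundTruth(
        effect_multipliers={g: config.effect_map.get(g, 1.0) for g in index.genes()},
        hit_genes=[g for g in index.genes() if config.effect_map.get(g, 1.0) != 1.0],
        expected_share=expected,
    )
    return matrix, truth


def emit_fastq(
    counts: CountMatrix,
    index: LibraryIndex,
    out_dir: str | Path,
    cassette: CassetteSpec | None = None,
    error_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, Path]:
    """Write one FASTQ per sample; each guide contributes exactly its count
    in reads (before substitution errors).

    Reads are upstream flank + spacer + downstream flank with a constant
    placeholder Phred quality. Substitution errors are applied per base at
    ``error_rate`` over the whole read. Returns sample_id -> path.
    """
    if not 0.0 <= error_rate < 1.0:
        raise SimulationError(f"error_rate must be in [0, 1), got {error_rate}")
    if cassette is None:
        cassette = CassetteSpec()
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bases = "ACGT"
    reads = {r.sgrna_id: cassette.read_for(r.spacer) for r in index.records}
    paths: dict[str, Path] = {}
    for sample_id in counts.sample_ids:
        path = out_dir / f"{sample_id}.fastq"
        col = counts.counts[sample_id]
        with open(path, "w", encoding="ascii") as fh:
            for sgrna_id, c in col.items():
                if c == 0:
                    continue
                seq = reads[sgrna_id]
                qual = "I" * len(seq)
                if error_rate == 0.0:
                    fh.write(f"@{sgrna_id}\n{seq}\n+\n{qual}\n" * int(c))
                    continue
                for k in range(int(c)):
                    hits = np.flatnonzero(rng.random(len(seq)) < error_rate)
                    if hits.size:
                        chars = list(seq)
                        for i in hits:
                            chars[i] = bases[(bases.index(chars[i]) + rng.integers(1, 4)) % 4]
                        mutated = "".join(chars)
                    else:
                        mutated = seq
                    fh.write(f"@{sgrna_id}:{k}\n{mutated}\n+\n{qual}\n")
        paths[sample_id] = path
    return paths


#: per-cluster (median, geometric spread) of the two channels, chosen so the
#: three populations are well separated on a log scale as in bead assays
DEFAULT_CLUSTER_PARAMS: dict[str, dict[str, float]] = {
    "PhagoNeg": {"yg_median": 100.0, "phrodo_median": 80.0, "sigma": 0.45},
    "PhagoEarly": {"yg_median": 5000.0, "phrodo_median": 100.0, "sigma": 0.45},
    "PhagoLate": {"yg_median": 5000.0, "phrodo_median": 4000.0, "sigma": 0.45},
}


def simulate_flow_events(
    n_events: int,
    fractions: Sequence[float],
    channel_params: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Mixture of three bivariate log-normal clusters of flow events.

    ``fractions`` = (PhagoNeg, PhagoEarly, PhagoLate) proportions, summing
    to 1. Returns a DataFrame with columns yg, phrodo and the ground-truth
    ``label`` per event.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape != (3,):
        raise SimulationError("fractions must be (negFrac, earlyFrac, lateFrac)")
    if (fractions < 0).any():
        raise SimulationError("fractions must be non-negative")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise SimulationError(f"fractions must sum to 1, got {fractions.sum()}")
    params = dict(DEFAULT_CLUSTER_PARAMS)
    if channel_params:
        for k, v in channel_params.items():
            params[k] = {**params[k], **v}
    rng = np.random.default_rng(seed)
    labels_all = np.array(["PhagoNeg", "PhagoEarly", "PhagoLate"])
    which = rng.choice(3, size=n_events, p=fractions)
    yg = np.empty(n_events)
    phrodo = np.empty(n_events)
    for i, lab in enumerate(labels_all):
        m = which == i
        p = params[lab]
        yg[m] = rng.lognormal(np.log(p["yg_median"]), p["sigma"], m.sum())
        phrodo[m] = rng.lognormal(np.log(p["phrodo_median"]), p["sigma"], m.sum())
    return pd.DataFrame({"yg": yg, "phrodo": phrodo, "label": labels_all[which]})


def bcecf_ratio(
    ph: np.ndarray | float, r_min: float, r_max: float, pka: float, hill: float
) -> np.ndarray | float:
    """Sigmoidal BCECF 490/440 emission ratio as a function of pH."""
    return r_min + (r_max - r_min) / (1.0 + 10.0 ** (hill * (pka - np.asarray(ph, float))))


def simulate_bcecf(
    curve_params: Mapping[str, float],
    ph_grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_phs: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Generate a calibration table (and optionally sample ratios) from the
    sigmoidal ratio-vs-pH model plus Gaussian noise.

    ``curve_params`` must provide r_min, r_max, pka, hill. Returns
    (calibration DataFrame with columns ph, ratio; sample DataFrame with
    columns true_ph, ratio, or None).
    """
    ph_grid = np.asarray(ph_grid, dtype=float)
    if ph_grid.size == 0:
        raise SimulationError("ph_grid must be non-empty")
    rng = np.random.default_rng(seed)
    p = curve_params
    ratios = bcecf_ratio(ph_grid, p["r_min"], p["r_max"], p["pka"], p["hill"])
    ratios = ratios + rng.normal(0.0, noise_sd, size=ph_grid.size)
    cal = pd.DataFrame({"ph": ph_grid, "ratio": ratios})
    samples = None
    if sample_phs is not None:
        sample_phs = np.asarray(sample_phs, dtype=float)
        r = bcecf_ratio(sample_phs, p["r_min"], p["r_max"], p["pka"], p["hill"])
        r = r + rng.normal(0.0, noise_sd, size=sample_phs.size)
        samples = pd.DataFrame({"true_ph": sample_phs, "ratio": r})
    return cal, samples
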