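"""Synthetic data with known ground truth for the TIL-reactivity workflow.

Three generators mirror the three data modalities the analysis consumes:

* flow-cytometry event tables for stimulated/control co-culture
  conditions, drawn from a mixture of functional classes (the 2^k
  CD137/TNF/IFNγ(/CD107a) positivity combinations) with two-component
  location–scale intensity distributions per channel;
* paired bulk expression (autologous vs allogeneic co-culture, one pair
  per patient) with a known set of spiked genes at stated log2
  fold-changes;
* sparse single-cell counts with binary marker-gene positivity classes
  and an activation-gene gradient that rises with the number of
  positive markers.

Every generator is deterministic given (config, seed) and returns a
:class:`SyntheticTruth` carrying the latent per-record labels so that
downstream estimates can be scored against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from . import flow
from .flow import ConfigurationError, EventTable

# Functional-class marker names (protein level).  CD137 here means total
# CD137; its surface/intracellular channel realization is drawn from the
# occupancy model below.
CLASS_MARKERS: tuple[str, ...] = ("CD137", "TNF", "IFNG", "CD107a")

ALL_NEGATIVE: frozenset[str] = frozenset()


def _class_key(markers) -> frozenset:
    key = frozenset(markers)
    unknown = key - set(CLASS_MARKERS)
    if unknown:
        raise ConfigurationError(f"class_fractions: unknown markers {sorted(unknown)}")
    return key


def class_label(key: frozenset) -> str:
    """Canonical string for a functional class, e.g. ``CD137+TNF-IFNG-CD107a-``."""
    return "".join(f"{m}{'+' if m in key else '-'}" for m in CLASS_MARKERS)


@dataclass(frozen=True)
class ChannelModel:
    """Two-component intensity model on the transformed (arcsinh-like) scale."""

    neg_loc: float = 0.5
    neg_scale: float = 0.35
    pos_loc: float = 3.5
    pos_scale: float = 0.5

    def validate(self, name: str) -> None:
        if self.pos_loc <= self.neg_loc:
            raise ConfigurationError(
                f"channel_params[{name}]: positive component location must exceed "
                f"the negative component location"
            )
        if self.neg_scale <= 0 or self.pos_scale <= 0:
            raise ConfigurationError(f"channel_params[{name}]: scales must be positive")


def _default_channel_params() -> dict[str, ChannelModel]:
    return {ch: ChannelModel() for ch in flow.ALL_CHANNELS}


def default_cd8_class_fractions() -> dict[frozenset, float]:
    """CD8 functional-class mixture: 41% reactive; within the reactive pool
    CD137 covers 74%, the CD137-only combination 21%, and the
    CD137/Antitumor-Function sub-grouping is 21/26/53."""
    within = {
        frozenset({"CD137"}): 0.21,
        frozenset({"TNF"}): 0.12,
        frozenset({"IFNG"}): 0.06,
        frozenset({"TNF", "IFNG"}): 0.08,
        frozenset({"CD137", "TNF"}): 0.18,
        frozenset({"CD137", "IFNG"}): 0.08,
        frozenset({"CD137", "TNF", "IFNG"}): 0.27,
    }
    reactive = 0.41
    out = {k: v * reactive for k, v in within.items()}
    out[ALL_NEGATIVE] = 1.0 - reactive
    return out


def default_cd4_class_fractions() -> dict[frozenset, float]:
    """CD4 mixture: 29% reactive; TNF covers 84% of the reactive pool and
    the CD137/Antitumor-Function sub-grouping is 5/69/26."""
    within = {
        frozenset({"CD137"}): 0.05,
        frozenset({"TNF"}): 0.45,
        frozenset({"IFNG"}): 0.09,
        frozenset({"TNF", "IFNG"}): 0.15,
        frozenset({"CD137", "TNF"}): 0.17,
        frozenset({"CD137", "IFNG"}): 0.02,
        frozenset({"CD137", "TNF", "IFNG"}): 0.07,
    }
    reactive = 0.29
    out = {k: v * reactive for k, v in within.items()}
    out[ALL_NEGATIVE] = 1.0 - reactive
    return out


def _default_inhibitor_effects() -> dict[str, tuple[float, float]]:
    # (surface multiplier, intracellular multiplier) on CD137 occupancy;
    # transport inhibition relocates CD137 detection rather than
    # abolishing it, so the total stays fixed.
    return {
        "none": (1.0, 1.0),
        "BFA": (0.24, 1.32),
        "MN": (0.98, 1.73),
        "BFA+MN": (0.21, 1.36),
    }


@dataclass
class FlowSimConfig:
    """Configuration of the flow-cytometry event simulator.

    ``class_fractions`` maps each subset to a mixture over functional
    classes (frozensets of positive markers among CD137/TNF/IFNG/CD107a)
    that must sum to 1.  ``background_rate`` is the per-marker spurious
    positivity rate of non-reactive cells (present in stimulated and
    control conditions alike, so background subtraction cancels it in
    expectation).  ``cd137_occupancy`` gives the no-inhibitor
    probabilities that a CD137+ cell stains surface- and
    intracellular-positive; inhibitors multiply these occupancies while
    conserving total CD137 positivity.
    """

    n_events: int = 50_000
    subset_mix: float = 0.6  # CD8 fraction; the rest are CD4
    class_fractions: dict[str, dict[frozenset, float]] = field(
        default_factory=lambda: {
            "CD8": default_cd8_class_fractions(),
            "CD4": default_cd4_class_fractions(),
        }
    )
    channel_params: dict[str, ChannelModel] = field(default_factory=_default_channel_params)
    background_rate: float = 2e-4
    dead_fraction: float = 0.03
    cd137_occupancy: tuple[float, float] = (0.90, 0.65)  # (surface, intracellular)
    inhibitor_effects: dict[str, tuple[float, float]] = field(
        default_factory=_default_inhibitor_effects
    )
    sample_id: str = "SIM"
    seed: int = 0

    def validate(self) -> None:
        if self.n_events <= 0:
            raise ConfigurationError("n_events must be positive")
        for name, rate in (
            ("subset_mix", self.subset_mix),
            ("background_rate", self.background_rate),
            ("dead_fraction", self.dead_fraction),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {rate}")
        for subset, fracs in self.class_fractions.items():
            normalized = {_class_key(k): v for k, v in fracs.items()}
            total = sum(normalized.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"class_fractions[{subset}] must sum to 1, got {total}"
                )
            if any(v < 0 for v in normalized.values()):
                raise ConfigurationError(f"class_fractions[{subset}] has negative entries")
        for ch, model in self.channel_params.items():
            model.validate(ch)
        s, ic = self.cd137_occupancy
        if not (0 < s <= 1 and 0 < ic <= 1):
            raise ConfigurationError("cd137_occupancy entries must lie in (0, 1]")


@dataclass
class SyntheticTruth:
    """Latent ground truth accompanying a synthetic dataset."""

    labels: object
    spiked: dict | None = None
    config: object = None


def _draw_classes(rng, fracs: dict[frozenset, float], n: int) -> list[frozenset]:
    keys = sorted(fracs, key=class_label)
    probs = np.array([fracs[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(keys), size=n, p=probs)
    return [keys[i] for i in idx]


def _intensity(rng, model: ChannelModel, positive: np.ndarray) -> np.ndarray:
    n = len(positive)
    neg = rng.normal(model.neg_loc, model.neg_scale, size=n)
    pos = rng.normal(model.pos_loc, model.pos_scale, size=n)
    return np.where(positive, pos, neg)


def _cd137_states(
    rng, n: int, occupancy: tuple[float, float], effect: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (surface, intracellular) positivity for CD137+ cells.

    Occupancies are multiplied by the inhibitor effect and the joint
    state distribution is reconstructed so that every CD137+ cell stays
    positive on at least one form (total CD137 conserved).
    """
    p_s = float(np.clip(occupancy[0] * effect[0], 0.0, 1.0))
    p_ic = float(np.clip(occupancy[1] * effect[1], 0.0, 1.0))
    if p_s + p_ic < 1.0:  # keep the union complete
        p_ic = 1.0 - p_s
    p_surface_only = 1.0 - p_ic
    p_ic_only = 1.0 - p_s
    p_both = p_s + p_ic - 1.0
    u = rng.random(n)
    surface = u < p_surface_only + p_both
    intracellular = u >= p_surface_only
    return surface, intracellular


def generate_flow_events(
    config: FlowSimConfig,
    conditions: Sequence[str] = flow.CONDITIONS,
    inhibitors: Sequence[str] = ("none",),
) -> tuple[dict[tuple[str, str], EventTable], SyntheticTruth]:
    """Simulate event tables for each (condition, inhibitor) combination.

    Stimulated (autologous) events draw their functional class from the
    configured mixture; control conditions (allogeneic, alone) contain
    only all-negative cells.  Non-reactive cells in every condition
    acquire spurious per-marker positivity at ``background_rate``.
    Returns the tables keyed by (condition, inhibitor) and the per-event
    latent truth (subset, class label, live flag).
    """
    config.validate()
    for inh in inhibitors:
        if inh not in config.inhibitor_effects:
            raise ConfigurationError(f"inhibitor_effects missing entry for {inh!r}")
    rng = np.random.default_rng(config.seed)
    tables: dict[tuple[str, str], EventTable] = {}
    truth_labels: dict[tuple[str, str], pd.DataFrame] = {}

    for condition in conditions:
        for inhibitor in inhibitors:
            n = config.n_events
            subset = np.where(rng.random(n) < config.subset_mix, "CD8", "CD4")
            dead = rng.random(n) < config.dead_fraction

            classes: list[frozenset] = [ALL_NEGATIVE] * n
            if condition == "autologous":
                for sub in ("CD8", "CD4"):
                    fracs = {_class_key(k): v for k, v in config.class_fractions[sub].items()}
                    mask = subset == sub
                    drawn = _draw_classes(rng, fracs, int(mask.sum()))
                    for i, j in enumerate(np.flatnonzero(mask)):
                        classes[j] = drawn[i]

            positive = {m: np.array([m in c for c in classes]) for m in CLASS_MARKERS}
            # spurious background positivity on non-reactive cells
            for m in CLASS_MARKERS:
                nonreactive = ~np.any([positive[k] for k in CLASS_MARKERS], axis=0)
                flips = nonreactive & (rng.random(n) < config.background_rate)
                positive[m] = positive[m] | flips

            surface = np.zeros(n, dtype=bool)
            intracellular = np.zeros(n, dtype=bool)
            cd137_idx = np.flatnonzero(positive["CD137"])
            if len(cd137_idx):
                s, ic = _cd137_states(
                    rng, len(cd137_idx), config.cd137_occupancy,
                    config.inhibitor_effects[inhibitor],
                )
                surface[cd137_idx] = s
                intracellular[cd137_idx] = ic

            cols = {}
            cols[flow.S_CD137] = _intensity(rng, config.channel_params[flow.S_CD137], surface)
            cols[flow.IC_CD137] = _intensity(
                rng, config.channel_params[flow.IC_CD137], intracellular
            )
            for m, ch in (("TNF", flow.TNF), ("IFNG", flow.IFNG), ("CD107a", flow.CD107A)):
                cols[ch] = _intensity(rng, config.channel_params[ch], positive[m])
            cols[flow.CD8] = _intensity(rng, config.channel_params[flow.CD8], subset == "CD8")
            cols[flow.CD4] = _intensity(rng, config.channel_params[flow.CD4], subset == "CD4")
            cols[flow.VIABILITY] = _intensity(rng, config.channel_params[flow.VIABILITY], dead)

            data = pd.DataFrame(cols)
            tables[(condition, inhibitor)] = EventTable(
                data=data,
                sample_id=config.sample_id,
                condition=condition,
                inhibitor=inhibitor,
            )
            truth_labels[(condition, inhibitor)] = pd.DataFrame(
                {
                    "subset": subset,
                    "class": [class_label(c) for c in classes],
                    "n_positive": [len(c) for c in classes],
                    "live": ~dead,
                }
            )
    return tables, SyntheticTruth(labels=truth_labels, config=config)


# ---------------------------------------------------------------------------
# paired bulk expression
# ---------------------------------------------------------------------------

@dataclass
class BulkSimConfig:
    """Configuration of the paired bulk-expression simulator.

    Each of ``n_pairs`` patients contributes one autologous and one
    allogeneic co-culture sample on the log2 scale; ``spiked_genes``
    maps gene names to their true mean log2 fold-change (autologous
    over allogeneic).  ``noise_sd`` is the per-sample residual SD.
    """

    n_genes: int = 2000
    n_pairs: int = 12
    spiked_genes: dict[str, float] = field(
        default_factory=lambda: {f"ACT{i:03d}": 3.0 for i in range(60)}
    )
    noise_sd: float = 0.5
    baseline_loc: float = 6.0
    baseline_scale: float = 2.0
    patient_sd: float = 0.3
    subset: str = "CD8"
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 2:
            raise ConfigurationError("n_pairs must be at least 2 (paired test undefined)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if len(self.spiked_genes) > self.n_genes:
            raise ConfigurationError("spiked_genes exceed the gene universe")

    def gene_names(self) -> list[str]:
        spiked = list(self.spiked_genes)
        n_null = self.n_genes - len(spiked)
        return spiked + [f"NULL{i:04d}" for i in range(n_null)]


@dataclass
class BulkExpressionPair:
    """Paired bulk expression: log2 matrix plus a samplesheet.

    ``matrix`` is genes × samples; ``samples`` has one row per sample
    with columns sample / patient / condition / subset, every patient
    contributing exactly one sample per condition.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame


def generate_bulk_pairs(config: BulkSimConfig) -> tuple[BulkExpressionPair, SyntheticTruth]:
    """Simulate paired autologous/allogeneic log2 expression per patient."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names()
    n_g, n_p = len(genes), config.n_pairs

    baseline = rng.normal(config.baseline_loc, config.baseline_scale, size=n_g)
    patient = rng.normal(0.0, config.patient_sd, size=n_p)
    lfc = np.array([config.spiked_genes.get(g, 0.0) for g in genes])

    allo = baseline[:, None] + patient[None, :] + rng.normal(0, config.noise_sd, (n_g, n_p))
    auto = (
        baseline[:, None] + patient[None, :] + lfc[:, None]
        + rng.normal(0, config.noise_sd, (n_g, n_p))
    )

    cols, rows = {}, []
    for p in range(n_p):
        pid = f"P{p + 1:02d}"
        for cond, mat in (("autologous", auto), ("allogeneic", allo)):
            sid = f"{pid}_{cond}"
            cols[sid] = mat[:, p]
            rows.append(
                {"sample": sid, "patient": pid, "condition": cond, "subset": config.subset}
            )
    matrix = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    samples = pd.DataFrame(rows)
    truth = SyntheticTruth(
        labels=samples, spiked=dict(config.spiked_genes), config=config
    )
    return BulkExpressionPair(matrix=matrix, samples=samples), truth


# ---------------------------------------------------------------------------
# single-cell counts
# ---------------------------------------------------------------------------

def default_sc_cluster_fractions(
    markers: Sequence[str] = ("TNFRSF9", "TNF", "IFNG"),
) -> dict[frozenset, float]:
    """Mixture over the 8 marker-positivity classes of in situ TILs."""
    m1, m2, m3 = markers
    return {
        frozenset(): 0.40,
        frozenset({m1}): 0.10,
        frozenset({m2}): 0.12,
        frozenset({m3}): 0.08,
        frozenset({m1, m2}): 0.05,
        frozenset({m1, m3}): 0.05,
        frozenset({m2, m3}): 0.05,
        frozenset({m1, m2, m3}): 0.15,
    }


@dataclass
class SCSimConfig:
    """Configuration of the single-cell count simulator.

    Cells belong to one of the 2^3 marker-positivity classes over
    ``marker_genes``; marker counts are strictly positive exactly in
    cells of classes declaring them positive (before dropout).
    Activation genes follow a negative-binomial with mean rising by
    ``gradient_log2_step`` log2 units per positive marker; *ENTPD1*
    positivity is coupled to *TNFRSF9* while *ITGAE* is independent.
    Dropout zeroes any count with probability ``dropout_rate``.
    """

    n_cells: int = 10_000
    subset: str = "CD8"
    marker_genes: tuple[str, str, str] = ("TNFRSF9", "TNF", "IFNG")
    specificity_genes: tuple[str, str] = ("ENTPD1", "ITGAE")
    cluster_fractions: dict[frozenset, float] | None = None
    entpd1_given_tnfrsf9: float = 0.65
    entpd1_base: float = 0.12
    itgae_rate: float = 0.35
    n_activation_genes: int = 50
    gradient_log2_step: float = 1.0
    activation_base_mean: float = 0.5
    n_noise_genes: int = 200
    noise_mean: float = 1.0
    nb_shape: float = 2.0
    marker_mean: float = 3.0
    dropout_rate: float = 0.0
    seed: int = 0

    def fractions(self) -> dict[frozenset, float]:
        if self.cluster_fractions is None:
            return default_sc_cluster_fractions(self.marker_genes)
        return {frozenset(k): v for k, v in self.cluster_fractions.items()}

    def activation_gene_names(self) -> list[str]:
        return [f"ACT{i:03d}" for i in range(self.n_activation_genes)]

    def noise_gene_names(self) -> list[str]:
        return [f"BG{i:04d}" for i in range(self.n_noise_genes)]

    def validate(self) -> None:
        if len(set(self.marker_genes)) != len(self.marker_genes):
            raise ConfigurationError("marker_genes must be unique")
        generated = set(self.activation_gene_names()) | set(self.noise_gene_names())
        clash = (set(self.marker_genes) | set(self.specificity_genes)) & generated
        if clash:
            raise ConfigurationError(f"marker gene name collision: {sorted(clash)}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must lie in [0, 1)")
        fracs = self.fractions()
        total = sum(fracs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"cluster_fractions must sum to 1, got {total}")
        unknown = set().union(*fracs) - set(self.marker_genes)
        if unknown:
            raise ConfigurationError(f"cluster_fractions name unknown markers {sorted(unknown)}")


def _nb_counts(rng, mean: np.ndarray | float, shape: float, size=None) -> np.ndarray:
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size) if size else np.asarray(mean)
    p = shape / (shape + np.maximum(mean, 1e-12))
    return rng.negative_binomial(shape, p)


def generate_sc_counts(config: SCSimConfig) -> tuple[ad.AnnData, SyntheticTruth]:
    """Simulate sparse single-cell counts with marker-positivity classes.

    Returns an AnnData (cells × genes, CSR integer counts, ``obs.subset``
    set) and the truth with per-cell class labels and positive-marker
    counts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    markers = list(config.marker_genes)

    fracs = config.fractions()
    keys = sorted(fracs, key=lambda k: "".join(sorted(k)))
    probs = np.array([fracs[k] for k in keys], dtype=float)
    probs /= probs.sum()
    idx = rng.choice(len(keys), size=n, p=probs)
    classes = [keys[i] for i in idx]
    pos = {m: np.array([m in c for c in classes]) for m in markers}
    n_pos = np.sum([pos[m] for m in markers], axis=0)

    columns: dict[str, np.ndarray] = {}
    for m in markers:
        counts = np.zeros(n, dtype=np.int64)
        k = int(pos[m].sum())
        if k:
            counts[pos[m]] = 1 + _nb_counts(rng, config.marker_mean, config.nb_shape, (k,))
        columns[m] = counts

    tnfrsf9 = pos[markers[0]]
    p_entpd1 = np.where(tnfrsf9, config.entpd1_given_tnfrsf9, config.entpd1_base)
    entpd1_pos = rng.random(n) < p_entpd1
    itgae_pos = rng.random(n) < config.itgae_rate
    for gene, gmask in zip(config.specificity_genes, (entpd1_pos, itgae_pos)):
        counts = np.zeros(n, dtype=np.int64)
        k = int(gmask.sum())
        if k:
            counts[gmask] = 1 + _nb_counts(rng, config.marker_mean, config.nb_shape, (k,))
        columns[gene] = counts

    act_genes = config.activation_gene_names()
    gene_scale = 2.0 ** rng.uniform(-0.5, 0.5, size=len(act_genes))
    step = 2.0 ** (config.gradient_log2_step * n_pos)
    for j, g in enumerate(act_genes):
        mean = config.activation_base_mean * gene_scale[j] * step
        columns[g] = _nb_counts(rng, mean, config.nb_shape, (n,))

    for g in config.noise_gene_names():
        columns[g] = _nb_counts(rng, config.noise_mean, config.nb_shape, (n,))

    X = np.column_stack([columns[g] for g in columns]).astype(np.int64)
    if config.dropout_rate > 0:
        X = np.where(rng.random(X.shape) < config.dropout_rate, 0, X)

    var_names = list(columns)
    obs = pd.DataFrame(
        {"subset": config.subset},
        index=pd.Index([f"cell{i:05d}" for i in range(n)], name="cell"),
    )
    adata = ad.AnnData(
        X=sparse.csr_matrix(X),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(var_names, name="gene")),
    )
    label_strings = [
        "".join(f"{m}{'+' if m in c else '-'}" for m in markers) for c in classes
    ]
    truth_df = pd.DataFrame(
        {
            "class": label_strings,
            "n_positive": n_pos,
            config.specificity_genes[0]: entpd1_pos,
            config.specificity_genes[1]: itgae_pos,
        },
        index=obs.index,
    )
    truth = SyntheticTruth(
        labels=truth_df,
        spiked={"activation_genes": act_genes},
        config=config,
    )
    return adata, truth
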