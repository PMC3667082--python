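"""Synthetic expression studies with planted signature structure.

The generator emulates the three datasets the concordance analysis consumes:

* a tumor matrix: a normal reference group plus k latent subtypes, each with
  a planted set of up/down marker genes shifted by +-delta (log2 units);
* an inducer matrix: control samples plus several "inducer" groups that all
  share a planted core signature (the EMT-like program) and carry small
  private responses, so that intersecting the per-inducer signatures
  recovers exactly the core;
* a paired matrix: positive/negative sorted sample pairs (CD133-like) whose
  planted signature opposes the core on a controlled fraction of core genes.

The correlation structure is planted explicitly: the first (mesenchymal-like)
subtype's markers overlap the core concordantly (``overlap_fraction``) and
overlap the anti-core/paired signature concordantly (``paired_overlap_fraction``
— which makes those genes *discordant* with the core).  This reproduces the
triangle the analysis is designed to detect: subtype ~ core, subtype ~
sorted signature, core vs. sorted signature anti-correlated.

All expression is Gaussian on the log2 scale: gene baselines ~
Normal(baseline_mean, baseline_sd), additive shifts, i.i.d. Normal(0,
noise_sd) measurement noise.  One integer seed drives everything; each
component uses its own fixed substream so adding a component never perturbs
earlier draws.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .signatures import GeneSignature

__all__ = ["SyntheticConfig", "SyntheticStudy", "generate_study", "truth_report"]

INDUCER_NAMES = ("TGFb", "Twist", "Gsc", "Snail", "shECad")
SUBTYPE_NAMES = ("mesenchymal", "classical", "neural", "proneural")
PAIR_NAMES = ("BT1", "BT2", "N1", "N2")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic study.

    Defaults describe the reference conditions used throughout the test
    suite: 5000 genes, 4 subtypes x 30 samples vs. 10 normals, a 200-gene
    core signature shared by 5 inducers, 4 sorted pairs, log2 effect size
    2.0 (four-fold) and measurement noise SD 0.3.
    """

    n_genes: int = 5000
    n_normal: int = 10
    samples_per_subtype: tuple[int, ...] = (30, 30, 30, 30)
    n_inducers: int = 5
    samples_per_inducer: int = 3
    n_inducer_controls: int = 3
    n_pairs: int = 4
    effect_size: float = 2.0  # delta, log2 units
    noise_sd: float = 0.3  # sigma, log2 units
    markers_per_subtype: int = 210
    core_signature_size: int = 200  # split evenly up/down
    overlap_fraction: float = 0.5  # rho: core genes concordantly in mesenchymal markers
    anti_fraction: float = 0.8  # fraction of core opposed by the paired signature
    paired_overlap_fraction: float = 0.4  # anti-core genes concordantly in mesenchymal markers
    pair_extra_genes: int = 120  # paired-signature genes outside the core
    inducer_private_genes: int = 50  # per-inducer genes outside the core
    missing_fraction: float = 0.02  # genes absent from each auxiliary dataset
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_genes, self.n_normal, self.n_inducers, self.samples_per_inducer,
            self.n_inducer_controls, self.n_pairs, self.markers_per_subtype,
            self.core_signature_size,
        )
        if any(c <= 0 for c in counts) or any(s <= 0 for s in self.samples_per_subtype):
            raise ValueError("all counts must be positive")
        for name in ("overlap_fraction", "anti_fraction", "paired_overlap_fraction",
                     "missing_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")

    @property
    def n_subtypes(self) -> int:
        return len(self.samples_per_subtype)


@dataclass
class StudyTruth:
    """Planted ground truth of a synthetic study."""

    subtype_signatures: dict[str, GeneSignature]
    core_signature: GeneSignature  # EMT-like program shared by all inducers
    inducer_signatures: dict[str, GeneSignature]  # core + private genes
    paired_signature: GeneSignature  # CD133-like, anti-correlated with the core
    config: SyntheticConfig


@dataclass
class SyntheticStudy:
    """Generated matrices, sample manifests, and the full ground truth."""

    expr_tumor: pd.DataFrame
    expr_inducers: pd.DataFrame
    expr_pairs: pd.DataFrame
    tumor_groups: pd.Series  # sample -> 'normal' | subtype name
    inducer_groups: pd.Series  # sample -> 'control' | inducer name
    pairs: list[tuple[str, str]]  # (positive, negative) sample ids
    truth: StudyTruth

    @property
    def normal_samples(self) -> list[str]:
        return self.tumor_groups.index[self.tumor_groups == "normal"].tolist()

    @property
    def subtype_labels(self) -> pd.Series:
        """Labels restricted to tumor (non-normal) samples."""
        mask = self.tumor_groups != "normal"
        return self.tumor_groups[mask]

    @property
    def control_samples(self) -> list[str]:
        return self.inducer_groups.index[self.inducer_groups == "control"].tolist()


def _names(prefix: str, n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"{prefix}_{i + 1:0{width}d}" for i in range(n)]


def _take(pool: list[str], n: int, what: str) -> list[str]:
    if n > len(pool):
        raise ValueError(f"not enough free genes for {what}: need {n}, have {len(pool)}")
    out = pool[:n]
    del pool[:n]
    return out


def generate_study(config: SyntheticConfig | None = None) -> SyntheticStudy:
    """Generate a fully specified synthetic study.  Deterministic given
    ``config.seed``."""
    cfg = config or SyntheticConfig()
    delta, sigma = cfg.effect_size, cfg.noise_sd

    # --- substreams: fixed offsets so components are independent ---
    rng_alloc = np.random.default_rng([cfg.seed, 0])
    rng_base = np.random.default_rng([cfg.seed, 1])
    rng_tumor = np.random.default_rng([cfg.seed, 2])
    rng_ind = np.random.default_rng([cfg.seed, 3])
    rng_pair = np.random.default_rng([cfg.seed, 4])
    rng_miss = np.random.default_rng([cfg.seed, 5])

    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    gene_pos = {g: i for i, g in enumerate(genes)}
    pool = [genes[i] for i in rng_alloc.permutation(cfg.n_genes)]

    # --- core (EMT-like) signature and its opposed (anti) subset ---
    n_core_up = cfg.core_signature_size // 2
    n_core_down = cfg.core_signature_size - n_core_up
    core_up = _take(pool, n_core_up, "core up")
    core_down = _take(pool, n_core_down, "core down")
    n_anti_up = round(cfg.anti_fraction * n_core_up)
    n_anti_down = round(cfg.anti_fraction * n_core_down)
    anti_up = [core_up[i] for i in rng_alloc.choice(n_core_up, n_anti_up, replace=False)]
    anti_down = [core_down[i] for i in rng_alloc.choice(n_core_down, n_anti_down, replace=False)]

    # --- subtype markers ---
    n_up = math.ceil(cfg.markers_per_subtype / 2)
    n_down = cfg.markers_per_subtype - n_up
    subtype_names = list(SUBTYPE_NAMES[: cfg.n_subtypes]) + [
        f"subtype{i + 1}" for i in range(len(SUBTYPE_NAMES), cfg.n_subtypes)
    ]
    markers: dict[str, tuple[list[str], list[str]]] = {}
    for s, name in enumerate(subtype_names):
        if s == 0:  # mesenchymal-like: planted overlap with core and anti-core
            n_conc_up = round(cfg.overlap_fraction * n_core_up)
            n_conc_down = round(cfg.overlap_fraction * n_core_down)
            n_disc_up = round(cfg.paired_overlap_fraction * n_anti_down)
            n_disc_down = round(cfg.paired_overlap_fraction * n_anti_up)
            if n_conc_up + n_disc_up > n_up or n_conc_down + n_disc_down > n_down:
                raise ValueError(
                    "planted core/anti-core overlaps exceed markers_per_subtype"
                )
            conc_up = [core_up[i] for i in rng_alloc.choice(n_core_up, n_conc_up, replace=False)]
            conc_down = [core_down[i] for i in rng_alloc.choice(n_core_down, n_conc_down, replace=False)]
            # discordant picks must avoid the concordant ones: a gene cannot
            # be both an up and a down marker of the same subtype
            free_anti_down = [g for g in anti_down if g not in set(conc_down)]
            free_anti_up = [g for g in anti_up if g not in set(conc_up)]
            n_disc_up = min(n_disc_up, len(free_anti_down))
            n_disc_down = min(n_disc_down, len(free_anti_up))
            disc_up = [free_anti_down[i] for i in rng_alloc.choice(len(free_anti_down), n_disc_up, replace=False)]
            disc_down = [free_anti_up[i] for i in rng_alloc.choice(len(free_anti_up), n_disc_down, replace=False)]
            up = conc_up + disc_up + _take(pool, n_up - n_conc_up - n_disc_up, f"{name} up")
            down = conc_down + disc_down + _take(pool, n_down - n_conc_down - n_disc_down, f"{name} down")
        else:
            up = _take(pool, n_up, f"{name} up")
            down = _take(pool, n_down, f"{name} down")
        markers[name] = (up, down)

    # --- inducer private responses and paired-signature extras ---
    inducer_names = list(INDUCER_NAMES[: cfg.n_inducers]) + [
        f"inducer{i + 1}" for i in range(len(INDUCER_NAMES), cfg.n_inducers)
    ]
    n_priv = cfg.inducer_private_genes // 2
    private: dict[str, tuple[list[str], list[str]]] = {
        name: (_take(pool, n_priv, "inducer private"), _take(pool, n_priv, "inducer private"))
        for name in inducer_names
    }
    n_extra = cfg.pair_extra_genes // 2
    extra_up = _take(pool, n_extra, "paired extra up")
    extra_down = _take(pool, n_extra, "paired extra down")

    paired_up = anti_down + extra_up  # opposite sign to the core
    paired_down = anti_up + extra_down

    # --- baselines ---
    mu = rng_base.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes)

    def build_matrix(columns: list[str], shifts: dict[str, list[tuple[list[str], float]]],
                     rng: np.random.Generator) -> pd.DataFrame:
        data = np.tile(mu[:, None], (1, len(columns))) + rng.normal(
            0.0, sigma, (cfg.n_genes, len(columns))
        )
        frame = pd.DataFrame(data, index=genes, columns=columns)
        for col, gene_shifts in shifts.items():
            j = columns.index(col)
            for gene_list, amount in gene_shifts:
                rows = [gene_pos[g] for g in gene_list]
                frame.iloc[rows, j] += amount
        return frame

    # --- tumor matrix ---
    normal_cols = _names("normal", cfg.n_normal)
    tumor_cols: list[str] = list(normal_cols)
    tumor_shifts: dict[str, list[tuple[list[str], float]]] = {}
    group_labels: dict[str, str] = {c: "normal" for c in normal_cols}
    for name, n_samples in zip(subtype_names, cfg.samples_per_subtype):
        cols = _names(name[:3], n_samples)
        up, down = markers[name]
        for c in cols:
            tumor_shifts[c] = [(up, delta), (down, -delta)]
            group_labels[c] = name
        tumor_cols += cols
    expr_tumor = build_matrix(tumor_cols, tumor_shifts, rng_tumor)

    # --- inducer matrix ---
    ctrl_cols = _names("ctrl", cfg.n_inducer_controls)
    ind_cols: list[str] = list(ctrl_cols)
    ind_shifts: dict[str, list[tuple[list[str], float]]] = {}
    ind_labels: dict[str, str] = {c: "control" for c in ctrl_cols}
    for name in inducer_names:
        cols = _names(name, cfg.samples_per_inducer)
        priv_up, priv_down = private[name]
        for c in cols:
            ind_shifts[c] = [
                (core_up, delta), (core_down, -delta),
                (priv_up, delta), (priv_down, -delta),
            ]
            ind_labels[c] = name
        ind_cols += cols
    expr_inducers = build_matrix(ind_cols, ind_shifts, rng_ind)

    # --- paired matrix ---
    pair_names = list(PAIR_NAMES[: cfg.n_pairs]) + [
        f"P{i + 1}" for i in range(len(PAIR_NAMES), cfg.n_pairs)
    ]
    pair_cols: list[str] = []
    pair_shifts: dict[str, list[tuple[list[str], float]]] = {}
    pairs: list[tuple[str, str]] = []
    for name in pair_names:
        pos, neg = f"{name}_pos", f"{name}_neg"
        pair_shifts[pos] = [(paired_up, delta), (paired_down, -delta)]
        pair_cols += [pos, neg]
        pairs.append((pos, neg))
    expr_pairs = build_matrix(pair_cols, pair_shifts, rng_pair)

    # --- per-dataset missing genes (never the planted ones) ---
    def drop_missing(frame: pd.DataFrame, protected: set[str]) -> pd.DataFrame:
        candidates = sorted(set(genes) - protected)
        n_drop = int(cfg.missing_fraction * len(candidates))
        if n_drop == 0:
            return frame
        dropped = rng_miss.choice(len(candidates), n_drop, replace=False)
        keep = set(candidates) - {candidates[i] for i in dropped}
        return frame.loc[[g for g in genes if g in keep or g in protected]]

    core_all = set(core_up) | set(core_down)
    priv_all = {g for ups, downs in private.values() for g in ups + downs}
    expr_inducers = drop_missing(expr_inducers, core_all | priv_all)
    expr_pairs = drop_missing(expr_pairs, set(paired_up) | set(paired_down))

    # --- ground truth signatures on each dataset's own universe ---
    tumor_universe = frozenset(expr_tumor.index)
    inducer_universe = frozenset(expr_inducers.index)
    pair_universe = frozenset(expr_pairs.index)
    truth = StudyTruth(
        subtype_signatures={
            name: GeneSignature(
                name=name, up=frozenset(markers[name][0]), down=frozenset(markers[name][1]),
                universe=tumor_universe,
            )
            for name in subtype_names
        },
        core_signature=GeneSignature(
            name="core", up=frozenset(core_up), down=frozenset(core_down),
            universe=inducer_universe,
        ),
        inducer_signatures={
            name: GeneSignature(
                name=name,
                up=frozenset(core_up) | frozenset(private[name][0]),
                down=frozenset(core_down) | frozenset(private[name][1]),
                universe=inducer_universe,
            )
            for name in inducer_names
        },
        paired_signature=GeneSignature(
            name="paired", up=frozenset(paired_up), down=frozenset(paired_down),
            universe=pair_universe,
        ),
        config=cfg,
    )
    return SyntheticStudy(
        expr_tumor=expr_tumor,
        expr_inducers=expr_inducers,
        expr_pairs=expr_pairs,
        tumor_groups=pd.Series(group_labels, name="group").loc[tumor_cols],
        inducer_groups=pd.Series(ind_labels, name="group").loc[ind_cols],
        pairs=pairs,
        truth=truth,
    )


def truth_report(study: SyntheticStudy) -> dict:
    """JSON-serializable ground truth for harness consumption."""

    def sig_dict(sig: GeneSignature) -> dict:
        return {"up": sorted(sig.up), "down": sorted(sig.down),
                "universe_size": len(sig.universe)}

    cfg = study.truth.config
    return {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in cfg.__dict__.items()},
        "tumor_groups": study.tumor_groups.to_dict(),
        "inducer_groups": study.inducer_groups.to_dict(),
        "pairs": [list(p) for p in study.pairs],
        "subtype_signatures": {k: sig_dict(v) for k, v in study.truth.subtype_signatures.items()},
        "core_signature": sig_dict(study.truth.core_signature),
        "inducer_signatures": {k: sig_dict(v) for k, v in study.truth.inducer_signatures.items()},
        "paired_signature": sig_dict(study.truth.paired_signature),
    }


def write_truth(study: SyntheticStudy, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth_report(study), indent=1))
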