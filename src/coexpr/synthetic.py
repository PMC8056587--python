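"""Synthetic RNA-seq corpora with known ground truth.

The generator emulates the statistical structure the rest of the pipeline
assumes, without any download: negative-binomial counts with a parametric
mean-dispersion trend ``alpha(mu) = a0 + a1/mu``, per-sample library-size
variation, and planted co-expression modules driven by latent factors.  For
each sample j, each active module m draws ``z_jm ~ Normal(0, latent_sd)``;
gene i's mean is ``mu_ij = sf_j * exp(b_i + sum_m lambda_im * z_jm)`` with
loadings drawn uniformly from the module's loading range for members (zero
otherwise), and counts are NB with that mean and trend dispersion.  Modules
can be restricted to specific tissue-disease groups (tissue-specific
co-expression) and given per-group log2 mean shifts (differential
expression between conditions).  The metadata table carries templated
free-text tissue descriptions that exercise the regex matcher, and
``total_reads`` equals the column sums of the generated matrix.

Three presets ship:

* ``strong`` — two clean 20-gene modules active everywhere; co-expression,
  enrichment, and topology signals are unambiguous.
* ``null`` — no modules; used for calibration tests.
* ``tissue-specific`` — six 10-gene modules each active in exactly one
  tissue-disease group, emulating tissue-restricted co-expression.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SimulationError
from .gsea import GeneSetCollection
from .normalize import CountMatrix

_CANCER_TEMPLATES = [
    "rna-seq of {tissue} tumor biopsy",
    "{tissue} carcinoma sample, bulk rna-seq",
    "primary {tissue} tumor tissue",
]
_NORMAL_TEMPLATES = [
    "bulk rna-seq of healthy {tissue} tissue",
    "normal {tissue} biopsy from donor",
    "{tissue} tissue, healthy control",
]


@dataclass
class GroupSpec:
    tissue: str
    disease: str
    n_samples: int

    @property
    def key(self) -> tuple[str, str]:
        return (self.tissue, self.disease)


@dataclass
class ModuleSpec:
    """A planted co-expression module.

    ``active_groups`` of None means the latent factor acts in every group;
    ``shift_groups`` adds a log2 mean shift to members in the named groups
    (differential expression, e.g. cancer-specific over-expression).
    """

    name: str
    size: int
    latent_sd: float = 1.0
    loading_range: tuple[float, float] = (0.35, 0.45)
    active_groups: list[tuple[str, str]] | None = None
    shift_groups: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class SimulationSpec:
    n_genes: int
    groups: list[GroupSpec]
    modules: list[ModuleSpec] = field(default_factory=list)
    dispersion_a0: float = 0.05
    dispersion_a1: float = 2.0
    baseline_log_mean_range: tuple[float, float] = (math.log(500.0), math.log(30000.0))
    library_size_log_sd: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_genes < 1:
            problems.append("n_genes must be >= 1")
        if not self.groups:
            problems.append("groups must be non-empty")
        if any(g.n_samples < 1 for g in self.groups):
            problems.append("every group needs n_samples >= 1")
        if len({g.key for g in self.groups}) != len(self.groups):
            problems.append("duplicate tissue-disease group")
        if self.dispersion_a0 < 0 or self.dispersion_a1 < 0:
            problems.append("dispersion parameters must be non-negative")
        if self.library_size_log_sd < 0:
            problems.append("library_size_log_sd must be non-negative")
        lo, hi = self.baseline_log_mean_range
        if not lo < hi:
            problems.append("baseline_log_mean_range must be increasing")
        total_module_genes = sum(m.size for m in self.modules)
        if total_module_genes > self.n_genes:
            problems.append("module genes exceed n_genes")
        group_keys = {g.key for g in self.groups}
        for m in self.modules:
            if m.size < 2:
                problems.append(f"module {m.name}: size must be >= 2")
            if m.loading_range[0] > m.loading_range[1]:
                problems.append(f"module {m.name}: loading_range must be ordered")
            for grp in (m.active_groups or []) + list(m.shift_groups):
                if tuple(grp) not in group_keys:
                    problems.append(f"module {m.name}: unknown group {grp}")
        if len({m.name for m in self.modules}) != len(self.modules):
            problems.append("module names must be unique")
        if problems:
            raise SimulationError("invalid simulation spec: " + "; ".join(problems))


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Gamma-Poisson mixture: mean mu, variance mu + alpha*mu^2."""
    counts = np.empty(mu.shape, dtype=np.int64)
    pois = alpha <= 1e-12
    if pois.any():
        counts[pois] = rng.poisson(mu[pois])
    if (~pois).any():
        lam = rng.gamma(shape=1.0 / alpha[~pois], scale=mu[~pois] * alpha[~pois])
        counts[~pois] = rng.poisson(lam)
    return counts


def simulate_counts(
    spec: SimulationSpec,
) -> tuple[CountMatrix, pd.DataFrame, dict]:
    """Generate (counts, metadata, truth) from a validated spec, reproducibly."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_genes = spec.n_genes
    gene_ids = np.array([f"G{i:04d}" for i in range(1, n_genes + 1)])

    sample_ids, sample_group = [], []
    for g in spec.groups:
        for _ in range(g.n_samples):
            sample_ids.append(f"S{len(sample_ids) + 1:05d}")
            sample_group.append(g.key)
    n_samples = len(sample_ids)
    sample_ids = np.array(sample_ids)

    lo, hi = spec.baseline_log_mean_range
    b = rng.uniform(lo, hi, size=n_genes)
    sf = np.exp(rng.normal(0.0, spec.library_size_log_sd, size=n_samples))

    # assign module genes as consecutive disjoint blocks
    membership: dict[str, list[str]] = {}
    loadings = np.zeros((len(spec.modules), n_genes))
    start = 0
    for mi, mod in enumerate(spec.modules):
        idx = np.arange(start, start + mod.size)
        start += mod.size
        membership[mod.name] = [str(g) for g in gene_ids[idx]]
        loadings[mi, idx] = rng.uniform(*mod.loading_range, size=mod.size)

    log_mu = np.tile(b[:, None], (1, n_samples))
    group_of = np.array([":".join(k) for k in sample_group])
    for mi, mod in enumerate(spec.modules):
        if mod.active_groups is None:
            active = np.ones(n_samples, dtype=bool)
        else:
            keys = {":".join(k) for k in mod.active_groups}
            active = np.isin(group_of, sorted(keys))
        z = np.where(active, rng.normal(0.0, mod.latent_sd, size=n_samples), 0.0)
        log_mu += loadings[mi][:, None] * z[None, :]
        for grp, shift in mod.shift_groups.items():
            cols = group_of == ":".join(grp)
            rows = loadings[mi] > 0
            log_mu[np.ix_(rows, cols)] += float(shift) * math.log(2.0)

    mu = np.exp(log_mu) * sf[None, :]
    alpha = spec.dispersion_a0 + spec.dispersion_a1 / mu
    counts = _nb_counts(rng, mu, alpha)

    rows = []
    for j, (sid, (tissue, disease)) in enumerate(zip(sample_ids, sample_group)):
        templates = _CANCER_TEMPLATES if disease == "cancer" else _NORMAL_TEMPLATES
        rows.append(
            {
                "sample_id": sid,
                "tissue_description": templates[j % len(templates)].format(tissue=tissue),
                "total_reads": int(counts[:, j].sum()),
            }
        )
    metadata = pd.DataFrame(rows)

    truth = {
        "seed": spec.seed,
        "n_genes": n_genes,
        "groups": [[g.tissue, g.disease, g.n_samples] for g in spec.groups],
        "dispersion": {"a0": spec.dispersion_a0, "a1": spec.dispersion_a1},
        "library_size_log_sd": spec.library_size_log_sd,
        "baseline_log_mean_range": list(spec.baseline_log_mean_range),
        "modules": {
            mod.name: {
                "genes": membership[mod.name],
                "latent_sd": mod.latent_sd,
                "loading_range": list(mod.loading_range),
                "active_groups": (
                    None
                    if mod.active_groups is None
                    else [list(k) for k in mod.active_groups]
                ),
                "shift_groups": {":".join(k): v for k, v in mod.shift_groups.items()},
            }
            for mod in spec.modules
        },
    }
    cm = CountMatrix(counts, gene_ids, sample_ids)
    return cm, metadata, truth


def modules_gmt(truth: dict) -> GeneSetCollection:
    """A small gene-set collection built from the planted modules."""
    return GeneSetCollection.from_dict(
        {name: info["genes"] for name, info in truth["modules"].items()},
        source_tag="planted-modules",
    )


def default_dictionaries(tissues: list[str]) -> dict:
    """Regex dictionaries matching the generator's description templates."""
    return {
        "tissues": {t: {"positive": [rf"\b{t}\b"], "negative": []} for t in sorted(tissues)},
        "disease": {
            "cancer": {
                "positive": ["tumor", "carcinoma", "sarcoma", "leukemia"],
                "negative": ["adjacent normal"],
            }
        },
        "scrna": {"scrna": {"positive": ["single cell", "scrna", "in-drop"]}},
    }


def preset(name: str, seed: int = 0) -> SimulationSpec:
    """Named study conditions: "strong", "null", or "tissue-specific"."""
    groups = [
        GroupSpec("bone", "cancer", 60),
        GroupSpec("bone", "normal", 60),
        GroupSpec("brain", "normal", 60),
    ]
    if name == "strong":
        modules = [
            ModuleSpec("M01", size=20, latent_sd=1.0, loading_range=(0.35, 0.45)),
            ModuleSpec("M02", size=20, latent_sd=1.0, loading_range=(0.35, 0.45)),
        ]
    elif name == "null":
        modules = []
    elif name == "tissue-specific":
        cycle = [g.key for g in groups]
        modules = [
            ModuleSpec(
                f"T{i + 1:02d}",
                size=10,
                latent_sd=1.5,
                loading_range=(0.6, 0.9),
                active_groups=[cycle[i % len(cycle)]],
            )
            for i in range(6)
        ]
    else:
        raise SimulationError(f"unknown preset {name!r}")
    return SimulationSpec(n_genes=1200, groups=groups, modules=modules, seed=seed)


def simulate_metadata_edge_cases() -> tuple[pd.DataFrame, dict]:
    """Deterministic metadata exercising every labelling and filtering rule.

    Contains: single-cell term hits ("in-drop", "scrna", "single cell"),
    read counts at 4,999,999 / 5,000,000 / 5,000,001, "kidney cortex"
    descriptions whose brain match is vetoed by the kidney negative term,
    a 29-member group (fully removed) and groups of >= 30 (retained).
    Returns (metadata table, dictionary JSON structure).
    """
    dicts = {
        "tissues": {
            "brain": {
                "positive": ["^pfc$", r"\bstriatum\b", "cortex", r"\bbrain\b"],
                "negative": ["kidney"],
            },
            "kidney": {"positive": ["kidney"], "negative": []},
            "bone": {"positive": [r"\bbone\b", "osteosarcoma"], "negative": []},
        },
        "disease": {
            "cancer": {
                "positive": ["tumor", "sarcoma", "carcinoma"],
                "negative": ["adjacent normal"],
            }
        },
        "scrna": {"scrna": {"positive": ["single cell", "scrna", "in-drop"]}},
    }
    rows = []

    def add(description: str, reads: int) -> None:
        rows.append(
            {
                "sample_id": f"E{len(rows) + 1:05d}",
                "tissue_description": description,
                "total_reads": reads,
            }
        )

    for i in range(33):  # retained brain-normal core
        desc = "bulk rna-seq of pfc tissue" if i % 2 == 0 else "striatum biopsy from healthy donor"
        add(desc, 6_000_000)
    add("bulk rna-seq of pfc tissue", 4_999_999)  # below the strict < 5M bound
    add("bulk rna-seq of pfc tissue", 5_000_000)  # exactly at the bound: retained
    add("bulk rna-seq of pfc tissue", 5_000_001)
    add("10x in-drop scrna-seq of cortex", 6_000_000)
    add("single cell suspension of brain cortex", 6_000_000)
    add("scrna-seq of striatum", 6_000_000)
    for _ in range(30):  # ambiguous-looking "kidney cortex": brain vetoed, kidney assigned
        add("rna-seq of kidney cortex tissue", 6_000_000)
    for _ in range(29):  # one sample short of the 30-sample rule
        add("osteosarcoma tumor biopsy", 6_000_000)
    return pd.DataFrame(rows), dicts


def write_dictionaries(dicts: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(dicts, fh, indent=1, sort_keys=True)
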