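"""Study-shaped synthetic data: compositions, phenotypes, planted effects.

The generator emulates a three-group diet-intervention design (control diet,
disease diet, treated disease diet; default group sizes 11/10/8). Each taxon
is drawn per sample from a gamma distribution moment-matched to its group's
target mean and SD on the percent scale, then rows are renormalized to
proportions; a filler taxon absorbs the remainder so partial taxon lists stay
compositional. Phenotypes are linear functions of designated standardized
taxon abundances plus Gaussian noise calibrated to a target correlation.

Packaged fixtures carry group mean/SD targets for a phylum-level and a
genus-level community, with a negative cholesterol coupling for a
Muribaculum-like taxon and a positive one for a Lactococcus-like taxon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .indicator import DEFAULT_MODELS, CodedModel
from .io import AbundanceTable, StudyDesign

__all__ = [
    "TaxonSpec",
    "PhenotypeSpec",
    "Coupling",
    "SyntheticSpec",
    "generate_study",
    "generate_null_study",
    "fixture_table",
    "planted_taxon",
    "write_spec",
    "read_spec",
]

FILLER_NAME = "other"


@dataclass(frozen=True)
class TaxonSpec:
    """Per-group mean/SD targets for one taxon, on the percent scale."""

    name: str
    mean: dict
    sd: dict


@dataclass(frozen=True)
class PhenotypeSpec:
    name: str
    mean: dict
    sd: dict


@dataclass(frozen=True)
class Coupling:
    """Target Pearson correlation between a taxon and a phenotype."""

    taxon: str
    phenotype: str
    r: float


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic study.

    ``group_sizes`` defaults to the 11/10/8 design. Per-group taxon means
    must sum to at most 100; the remainder goes to a filler taxon with zero
    SD. ``noise_model`` selects independent gamma draws with row
    renormalization (default; matches arbitrary mean/SD targets) or a joint
    Dirichlet draw (compositionally exact, but SD targets become a single
    concentration knob).
    """

    taxa: tuple
    group_order: tuple = ("ND", "WD", "WD-T070")
    group_sizes: dict = field(default_factory=lambda: {"ND": 11, "WD": 10, "WD-T070": 8})
    phenotypes: tuple = ()
    couplings: tuple = ()
    noise_model: str = "gamma_renormalized"
    dirichlet_concentration: float = 100.0
    level: str | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.noise_model not in ("gamma_renormalized", "dirichlet"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        for t in self.taxa:
            for g in self.group_order:
                if t.mean.get(g, 0) < 0 or t.sd.get(g, 0) < 0:
                    raise ValueError(f"negative mean/SD for taxon {t.name!r}")
        for g in self.group_order:
            total = sum(t.mean.get(g, 0.0) for t in self.taxa)
            if total > 100 + 1e-9:
                raise ValueError(f"group {g!r} taxon means sum to {total} > 100")
        for c in self.couplings:
            if abs(c.r) >= 1:
                raise ValueError(f"infeasible coupling |r| >= 1 for {c.taxon!r}")

    @property
    def taxon_names(self) -> list:
        return [t.name for t in self.taxa]


def _sample_ids(spec: SyntheticSpec) -> tuple[list, np.ndarray]:
    ids, labels = [], []
    for g in spec.group_order:
        for i in range(spec.group_sizes[g]):
            ids.append(f"{g}_{i + 1:02d}")
            labels.append(g)
    return ids, np.array(labels)


def _gamma_draw(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size)
    if sd <= 0:
        return np.full(size, mean)
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return rng.gamma(shape, scale, size=size)


def _compositions(spec: SyntheticSpec, rng: np.random.Generator,
                  group_of_sample: np.ndarray) -> pd.DataFrame:
    names = spec.taxon_names + [FILLER_NAME]
    n = len(group_of_sample)
    raw = np.zeros((n, len(names)))
    for g in spec.group_order:
        mask = group_of_sample == g
        n_g = int(mask.sum())
        means = np.array([t.mean.get(g, 0.0) for t in spec.taxa])
        sds = np.array([t.sd.get(g, 0.0) for t in spec.taxa])
        filler = max(0.0, 100.0 - means.sum())
        if spec.noise_model == "dirichlet":
            fractions = np.append(means, filler) / 100.0
            alpha = np.clip(fractions, 1e-9, None) * spec.dirichlet_concentration
            raw[mask] = rng.dirichlet(alpha, size=n_g) * 100.0
        else:
            block = np.column_stack(
                [_gamma_draw(rng, m, s, n_g) for m, s in zip(means, sds)]
                + [np.full(n_g, filler)]
            )
            raw[mask] = block
    totals = raw.sum(axis=1)
    totals[totals == 0] = 1.0
    rel = raw / totals[:, None]
    return pd.DataFrame(rel, columns=names)


def _phenotypes(spec: SyntheticSpec, rng: np.random.Generator,
                composition: pd.DataFrame, group_of_sample: np.ndarray,
                couple: bool = True) -> pd.DataFrame:
    n = len(group_of_sample)
    out = {}
    for ph in spec.phenotypes:
        couplings = [c for c in spec.couplings if c.phenotype == ph.name] if couple else []
        signal = np.zeros(n)
        var_signal = 0.0
        for c in couplings:
            x = composition[c.taxon].to_numpy()
            if np.ptp(x) == 0:
                continue
            z = (x - x.mean()) / x.std()
            signal += c.r * z
            var_signal += c.r ** 2
        noise_sd = np.sqrt(max(0.0, 1.0 - var_signal))
        w = signal + noise_sd * rng.standard_normal(n)
        mean = np.array([ph.mean[g] for g in group_of_sample])
        sd = np.array([ph.sd[g] for g in group_of_sample])
        out[ph.name] = mean + sd * w
    return pd.DataFrame(out)


def generate_study(spec: SyntheticSpec, seed: int | None = None
                   ) -> tuple[AbundanceTable, StudyDesign, pd.DataFrame]:
    """Draw one synthetic study: abundances, design, phenotypes.

    Fully reproducible given ``seed``. Rows of the abundance table are
    proportions summing to 1.
    """
    rng = np.random.default_rng(seed)
    ids, labels = _sample_ids(spec)
    comp = _compositions(spec, rng, labels)
    comp.index = pd.Index(ids, name="sample_id")
    table = AbundanceTable(data=comp, mode="relative", level=spec.level)
    design = StudyDesign(assignments=pd.Series(labels, index=ids),
                         group_order=spec.group_order)
    pheno = _phenotypes(spec, rng, comp, labels)
    pheno.index = comp.index
    return table, design, pheno


def generate_null_study(spec: SyntheticSpec, seed: int | None = None
                        ) -> tuple[AbundanceTable, StudyDesign, pd.DataFrame]:
    """As :func:`generate_study`, but every group is drawn from the control
    distribution and phenotypes are independent of all taxa."""
    rng = np.random.default_rng(seed)
    ids, labels = _sample_ids(spec)
    control = spec.group_order[0]
    null_taxa = tuple(
        TaxonSpec(t.name,
                  {g: t.mean.get(control, 0.0) for g in spec.group_order},
                  {g: t.sd.get(control, 0.0) for g in spec.group_order})
        for t in spec.taxa
    )
    null_phen = tuple(
        PhenotypeSpec(p.name,
                      {g: p.mean[control] for g in spec.group_order},
                      {g: p.sd[control] for g in spec.group_order})
        for p in spec.phenotypes
    )
    null_spec = SyntheticSpec(
        taxa=null_taxa, group_order=spec.group_order, group_sizes=spec.group_sizes,
        phenotypes=null_phen, couplings=(), noise_model=spec.noise_model,
        dirichlet_concentration=spec.dirichlet_concentration, level=spec.level,
    )
    comp = _compositions(null_spec, rng, labels)
    comp.index = pd.Index(ids, name="sample_id")
    table = AbundanceTable(data=comp, mode="relative", level=spec.level)
    design = StudyDesign(assignments=pd.Series(labels, index=ids),
                         group_order=spec.group_order)
    pheno = _phenotypes(null_spec, rng, comp, labels, couple=False)
    pheno.index = comp.index
    return table, design, pheno


def planted_taxon(name: str, model: CodedModel | int, target_r2: float,
                  scale: float = 0.03,
                  group_order: tuple = ("ND", "WD", "WD-T070"),
                  group_sizes: dict | None = None) -> TaxonSpec:
    """A taxon whose group means follow one coding at a chosen effect size.

    Group means are the model's codes times ``scale`` (percent); the shared
    within-group SD is set so the expected coded-fit r^2 —
    between-group variance / (between + within) under the study's group
    sizes — equals ``target_r2``.
    """
    if isinstance(model, int):
        model = DEFAULT_MODELS[model - 1]
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must lie in (0, 1)")
    if group_sizes is None:
        group_sizes = {"ND": 11, "WD": 10, "WD-T070": 8}
    means = {g: c * scale for g, c in zip(group_order, model.codes)}
    per_sample = np.concatenate([
        np.full(group_sizes[g], means[g]) for g in group_order
    ])
    var_between = per_sample.var()
    sigma = np.sqrt(var_between * (1 - target_r2) / target_r2)
    return TaxonSpec(name, means, {g: sigma for g in group_order})


# ------------------------------------------------------------- fixtures

def _spec_from_dict(d: dict) -> SyntheticSpec:
    return SyntheticSpec(
        taxa=tuple(TaxonSpec(t["name"], dict(t["mean"]), dict(t["sd"]))
                   for t in d["taxa"]),
        group_order=tuple(d.get("group_order", ("ND", "WD", "WD-T070"))),
        group_sizes=dict(d.get("group_sizes", {"ND": 11, "WD": 10, "WD-T070": 8})),
        phenotypes=tuple(PhenotypeSpec(p["name"], dict(p["mean"]), dict(p["sd"]))
                         for p in d.get("phenotypes", [])),
        couplings=tuple(Coupling(c["taxon"], c["phenotype"], float(c["r"]))
                        for c in d.get("couplings", [])),
        noise_model=d.get("noise_model", "gamma_renormalized"),
        dirichlet_concentration=float(d.get("dirichlet_concentration", 100.0)),
        level=d.get("level"),
        name=d.get("name"),
    )


def _spec_to_dict(spec: SyntheticSpec) -> dict:
    return {
        "name": spec.name,
        "level": spec.level,
        "group_order": list(spec.group_order),
        "group_sizes": dict(spec.group_sizes),
        "noise_model": spec.noise_model,
        "dirichlet_concentration": spec.dirichlet_concentration,
        "taxa": [{"name": t.name, "mean": dict(t.mean), "sd": dict(t.sd)}
                 for t in spec.taxa],
        "phenotypes": [{"name": p.name, "mean": dict(p.mean), "sd": dict(p.sd)}
                       for p in spec.phenotypes],
        "couplings": [{"taxon": c.taxon, "phenotype": c.phenotype, "r": c.r}
                      for c in spec.couplings],
    }


def write_spec(spec: SyntheticSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_spec_to_dict(spec), fh, sort_keys=False)


def read_spec(path) -> SyntheticSpec:
    with open(path) as fh:
        return _spec_from_dict(yaml.safe_load(fh))


def fixture_table(name: str) -> SyntheticSpec:
    """Packaged fixture spec: ``phylum_table2`` or ``genus_table3``.

    The fixtures carry per-group mean/SD targets for a phylum-level
    community (10 phyla) and a genus-level community (26 genera), with
    cholesterol couplings of opposite sign for the Muribaculum-like and
    Lactococcus-like genera.
    """
    valid = {"phylum_table2", "genus_table3"}
    if name not in valid:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(valid)}")
    ref = resources.files("rescuetax") / "fixtures" / f"{name}.yaml"
    return _spec_from_dict(yaml.safe_load(ref.read_text()))
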