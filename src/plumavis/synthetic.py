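"""Synthetic study inputs with known ground truth.

The generator emulates the structure of a comparative plumage-colour
study on a small passerine radiation: ~15 species plus ~9 subspecies,
reflectance spectra for seven body patches per sex built from
phenomenological colour templates (structural UV/blue peak, carotenoid
step, melanin ramp), green-leaf and brown-bark background spectra, a
posterior cloud of ultrametric trees, habitat covariates dominated by a
single vegetation factor that also drives latitude and rainfall, and
taxon-level contrast responses generated under a known regression effect
with tunable phylogenetic signal.

Defaults mirror the emulated study's conditions: 15 species, 9 grafted
subspecies, 16 individuals per sex per taxon, 1-2 replicate spectra per
patch, seven patches, and effect sizes in the low-JND-per-PC-unit range.
Spectra are generated on a 1-nm grid so the 5-nm down-sampling path is
exercised.  Every output is a deterministic function of (config, seed).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from plumavis.habitat import pca_covariance
from plumavis.phylo import TreeSamplePosterior, phylo_covariance
from plumavis.spectra import PATCHES, ReflectanceSpectrum, SpectrumMeta

GRID_1NM = np.arange(300.0, 701.0, 1.0)

TEMPLATE_NAMES = ("structural", "carotenoid", "melanin")


# ---------------------------------------------------------------------------
# Spectral templates (percent reflectance on any wavelength grid)


def structural_template(wl, peak: float = 390.0, sigma: float = 45.0,
                        amplitude: float = 50.0, baseline: float = 3.0):
    """UV/blue structural colour: Gaussian peak over a dark baseline.

    Peaks are drawn from 350-410 nm by default: within that band a
    Gaussian of width 30-60 nm keeps more than 30% of its reflectance
    below 400 nm, so structural patches exceed the UV-chroma criterion
    with margin; peaks much above ~415 nm mathematically cannot.
    """
    wl = np.asarray(wl, dtype=float)
    return baseline + amplitude * np.exp(-((wl - peak) ** 2) / (2 * sigma**2))


def carotenoid_template(wl, step: float = 550.0, width: float = 20.0,
                        amplitude: float = 45.0, baseline: float = 5.0):
    """Carotenoid red/orange: sigmoid step up near 550 nm."""
    wl = np.asarray(wl, dtype=float)
    return baseline + amplitude / (1.0 + np.exp(-(wl - step) / width))


def melanin_template(wl, low: float = 4.0, high: float = 12.0):
    """Melanin brown/black: low, monotonically rising ramp."""
    wl = np.asarray(wl, dtype=float)
    return low + (high - low) * (wl - 300.0) / 400.0


def green_background_template(wl):
    """Green foliage: reflectance peak near 550 nm over a low baseline."""
    wl = np.asarray(wl, dtype=float)
    return 4.0 + 16.0 * np.exp(-((wl - 550.0) ** 2) / (2 * 40.0**2))


def brown_background_template(wl):
    """Brown bark / soil: monotonically increasing reflectance."""
    wl = np.asarray(wl, dtype=float)
    return 5.0 + 25.0 * (wl - 300.0) / 400.0


_TEMPLATES = {
    "structural": structural_template,
    "carotenoid": carotenoid_template,
    "melanin": melanin_template,
    "green_background": green_background_template,
    "brown_background": brown_background_template,
}


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class EffectModel:
    """True regression structure behind generated taxon-level responses."""

    beta_pc: float = 0.15       # JND change per unit of vegetation PC
    beta_lat: float = 0.0       # JND change per degree latitude
    intercept: float = 5.0      # baseline contrast, JND
    s2_phylo: float = 0.2
    s2_species: float = 0.05
    s2_resid: float = 0.1

    def __post_init__(self):
        if min(self.s2_phylo, self.s2_species, self.s2_resid) < 0:
            raise ValueError("variance components must be nonnegative")


@dataclass
class GeneratorConfig:
    n_species: int = 15
    n_subspecies: int = 9
    n_individuals: int = 16      # per sex per taxon
    n_trees: int = 1300
    replicates: tuple = (1, 2)   # replicate spectra per (individual, patch)
    noise_sd: float = 1.0        # measurement noise, percent reflectance
    tree_jitter: float = 0.05    # log-normal branch jitter sd
    nni_prob: float = 0.1        # NNI move probability per posterior clone
    structural_peak_range: tuple = (350.0, 410.0)
    structural_sigma_range: tuple = (30.0, 60.0)
    p_structural: dict = field(
        default_factory=lambda: {"F": 0.085, "M": 0.30}
    )
    p_carotenoid: dict = field(default_factory=lambda: {"F": 0.10, "M": 0.20})
    effect: EffectModel = field(default_factory=EffectModel)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Trees


def _nni(tree, rng: random.Random) -> None:
    """One random nearest-neighbour-interchange on an internal edge."""
    internal = [
        n for n in tree.preorder_node_iter()
        if n.parent_node is not None
        and n.parent_node.parent_node is not None
        and not n.is_leaf()
    ]
    if not internal:
        return
    node = rng.choice(internal)
    parent = node.parent_node
    siblings = [c for c in parent.child_nodes() if c is not node]
    if not siblings:
        return
    sib = rng.choice(siblings)
    child = rng.choice(node.child_nodes())
    parent.remove_child(sib)
    node.remove_child(child)
    node.add_child(sib)
    parent.add_child(child)


def _rescale_height(tree, height: float = 1.0) -> None:
    depths = {}
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    h = max(l.root_distance for l in tree.leaf_node_iter())
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length *= height / h


def _ensure_min_terminal(tree, min_term: float = 0.06) -> None:
    """Uniformly extend all tip branches so the shortest terminal branch is
    at least ``min_term`` after rescaling back to height 1.

    Keeps the tree ultrametric (all tip depths grow by the same amount)
    and guarantees room for subspecies grafting at branch length 0.025.
    """
    terms = [l.edge.length for l in tree.leaf_node_iter()]
    shortest = min(terms)
    if shortest >= min_term:
        return
    delta = (min_term - shortest) / (1.0 - min_term)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += delta
    _rescale_height(tree, 1.0)


def gen_tree_posterior(
    n_species: int = 15,
    n_trees: int = 1300,
    jitter: float = 0.05,
    nni_prob: float = 0.1,
    n_subspecies: int = 9,
    seed: int = 0,
) -> tuple[TreeSamplePosterior, pd.DataFrame]:
    """A pure-birth base tree (height 1) plus jittered posterior clones.

    Clones get independent log-normal branch-length jitter, optional NNI
    moves with the given probability, and are re-ultrametrized to height
    1.  Also returns a grafting table assigning ``n_subspecies``
    subspecies round-robin to the first species.
    """
    pyrng = random.Random(seed)
    ns = dendropy.TaxonNamespace([f"sp{i + 1:02d}" for i in range(n_species)])
    base = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_species,
        taxon_namespace=ns, rng=pyrng,
    )
    _rescale_height(base, 1.0)
    _ensure_min_terminal(base)
    nprng = np.random.default_rng(seed)
    trees = []
    for _ in range(n_trees):
        clone = base.clone(depth=1)
        if jitter > 0:
            for e in clone.preorder_edge_iter():
                if e.length is not None:
                    e.length *= float(nprng.lognormal(0.0, jitter))
        if nni_prob > 0 and pyrng.random() < nni_prob:
            _nni(clone, pyrng)
        # extend tips to the deepest leaf, then rescale to height 1
        clone.calc_node_root_distances(return_leaf_distances_only=False)
        h = max(l.root_distance for l in clone.leaf_node_iter())
        for leaf in clone.leaf_node_iter():
            leaf.edge.length += h - leaf.root_distance
        _rescale_height(clone, 1.0)
        _ensure_min_terminal(clone)
        trees.append(clone)
    species = [t.label for t in ns]
    grafting = pd.DataFrame({
        "species": [species[i % n_species] for i in range(n_subspecies)],
        "subspecies": [
            f"{species[i % n_species]}_ssp{i // n_species + 1}"
            for i in range(n_subspecies)
        ],
    })
    return TreeSamplePosterior(trees=trees, taxon_labels=tuple(sorted(species))), grafting


# ---------------------------------------------------------------------------
# Habitat


def gen_habitat(taxa, seed: int = 0, env_noise_sd: float = 0.04) -> pd.DataFrame:
    """Habitat table with a dominant shared vegetation factor.

    A latent vegetation score v ~ N(0, 1) per taxon drives the three
    environmental variables (loadings 0.5, 0.45, 0.7 with small
    independent noise so PC1 dominates), latitude (r^2 ~ 0.5 with v),
    rainfall (r^2 ~ 0.6) and an uncorrelated temperature.
    """
    taxa = list(taxa)
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(len(taxa))
    loadings = (0.5, 0.45, 0.7)
    df = pd.DataFrame({
        f"env{k + 1}": a * v + rng.normal(0.0, env_noise_sd, len(taxa))
        for k, a in enumerate(loadings)
    }, index=pd.Index(taxa, name="taxon_id"))
    df["latitude"] = -25.0 + 7.5 * v + rng.normal(0.0, 7.5, len(taxa))
    df["rainfall"] = 900.0 + 350.0 * v + rng.normal(0.0, 300.0, len(taxa))
    df["temperature"] = 22.0 + rng.normal(0.0, 3.0, len(taxa))
    df.attrs["latent_vegetation"] = v
    return df


# ---------------------------------------------------------------------------
# Responses


def species_of(taxon: str) -> str:
    """Taxon naming convention: subspecies are '<species>_sspN'."""
    return taxon.split("_ssp")[0]


def gen_responses(
    tree,
    habitat: pd.DataFrame,
    effect: EffectModel | None = None,
    seed: int = 0,
    patches=PATCHES,
) -> tuple[pd.DataFrame, dict]:
    """Taxon x patch responses under a known mixed-model structure.

    response = intercept + beta_pc * PC + beta_lat * latitude + patch
    offset + phylogenetic deviate (multivariate normal, covariance
    s2_phylo * C(tree)) + species deviate + residual.  Returns the long
    table and a truth record holding every parameter and deviate.
    """
    effect = effect or EffectModel()
    rng = np.random.default_rng(seed)
    taxa = sorted(habitat.index)
    pc = pca_covariance(habitat.loc[taxa]).scores
    labels, C = phylo_covariance(tree, labels=taxa)
    u_phylo = rng.multivariate_normal(
        np.zeros(len(taxa)), effect.s2_phylo * C, method="cholesky"
    ) if effect.s2_phylo > 0 else np.zeros(len(taxa))
    species = sorted({species_of(t) for t in taxa})
    u_species = {
        s: rng.normal(0.0, np.sqrt(effect.s2_species)) for s in species
    }
    patch_offsets = dict(zip(patches, np.linspace(-0.3, 0.3, len(patches))))
    rows = []
    for i, t in enumerate(taxa):
        for p in patches:
            resp = (
                effect.intercept
                + effect.beta_pc * pc[t]
                + effect.beta_lat * habitat.loc[t, "latitude"]
                + patch_offsets[p]
                + u_phylo[i]
                + u_species[species_of(t)]
                + rng.normal(0.0, np.sqrt(effect.s2_resid))
            )
            rows.append({
                "taxon_id": t, "patch": p, "response": resp,
                "vegetation_pc": pc[t],
                "latitude": habitat.loc[t, "latitude"],
            })
    truth = {
        "effect": asdict(effect),
        "u_phylo": dict(zip(taxa, u_phylo)),
        "u_species": u_species,
        "patch_offsets": patch_offsets,
        "seed": seed,
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Spectra


def assign_patch_templates(taxa, config: GeneratorConfig, seed: int = 0) -> pd.DataFrame:
    """Assign a colour template to every (taxon, sex, patch).

    Structural and carotenoid probabilities are sex-specific (males carry
    far more structural colour in the emulated system); the remainder is
    melanin.  Structural peak and width are drawn per assignment from
    the 350-450 nm / 30-60 nm ranges.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for taxon in taxa:
        for sex in ("F", "M"):
            for patch in PATCHES:
                u = rng.random()
                ps = config.p_structural[sex]
                pc = config.p_carotenoid[sex]
                if u < ps:
                    template = "structural"
                elif u < ps + pc:
                    template = "carotenoid"
                else:
                    template = "melanin"
                rows.append({
                    "taxon_id": taxon, "sex": sex, "patch": patch,
                    "template": template,
                    "peak": float(rng.uniform(*config.structural_peak_range)),
                    "sigma": float(rng.uniform(*config.structural_sigma_range)),
                    "intensity": float(rng.uniform(0.8, 1.2)),
                })
    return pd.DataFrame(rows)


def template_curve(row, wl) -> np.ndarray:
    if row["template"] == "structural":
        base = structural_template(wl, peak=row["peak"], sigma=row["sigma"])
    else:
        base = _TEMPLATES[row["template"]](wl)
    return row["intensity"] * base


def gen_spectra(
    assignments: pd.DataFrame, config: GeneratorConfig, seed: int = 0
) -> tuple[list, pd.DataFrame]:
    """Measurement-level spectra on a 1-nm grid from template assignments.

    Per (taxon, sex, patch): ``n_individuals`` specimens, each with 1-2
    replicates of template x intensity plus Gaussian measurement noise,
    clamped at zero.  Returns (list of ReflectanceSpectrum, metadata
    table); the assignment table is the truth record for which patches
    are structural.
    """
    rng = np.random.default_rng(seed)
    spectra, meta_rows = [], []
    counter = 0
    for _, row in assignments.iterrows():
        curve = template_curve(row, GRID_1NM)
        for ind in range(config.n_individuals):
            ind_id = f"{row['taxon_id']}_{row['sex']}{ind + 1:02d}"
            n_rep = int(rng.integers(config.replicates[0], config.replicates[1] + 1))
            for rep in range(n_rep):
                counter += 1
                mid = f"m{counter:06d}"
                r = curve + rng.normal(0.0, config.noise_sd, GRID_1NM.size)
                r = np.clip(r, 0.0, None)
                meta = SpectrumMeta(
                    measurement_id=mid, taxon_id=row["taxon_id"],
                    sex=row["sex"], individual_id=ind_id,
                    patch=row["patch"], replicate=rep + 1,
                )
                spectra.append(ReflectanceSpectrum(GRID_1NM.copy(), r, meta))
                meta_rows.append({
                    "measurement_id": mid, "taxon_id": row["taxon_id"],
                    "sex": row["sex"], "individual_id": ind_id,
                    "patch": row["patch"], "replicate": rep + 1,
                })
    return spectra, pd.DataFrame(meta_rows)


def gen_backgrounds(grid=None) -> tuple[ReflectanceSpectrum, ReflectanceSpectrum]:
    """Noiseless green-foliage and brown-bark background spectra."""
    wl = GRID_1NM if grid is None else np.asarray(grid, dtype=float)
    green = ReflectanceSpectrum(
        wl.copy(), green_background_template(wl),
        SpectrumMeta("bg_green", "background", "F", "bg", "head"),
    )
    brown = ReflectanceSpectrum(
        wl.copy(), brown_background_template(wl),
        SpectrumMeta("bg_brown", "background", "F", "bg", "head"),
    )
    return green, brown
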