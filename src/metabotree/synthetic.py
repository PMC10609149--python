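"""Seeded generator of hierarchical labeled descriptor datasets.

The generated structure mirrors what the classification tree assumes: a
top-level NS vs SC split that can be made nonlinear (concentric radial
shells, not linearly separable) or linear (mean shift), and a sub-split of
NS into AD vs SQ by a mean shift on a separate block of informative
dimensions.  The remaining dimensions are pure noise.  p-values and fold
changes are drawn so that a configurable fraction of records passes the
significance filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import (
    DescriptorMatrix,
    LabeledDataset,
    MetaboliteRecord,
    MetaboliteTable,
    SubLabel,
    TopLabel,
)
from .errors import ValidationError

__all__ = ["SyntheticSpec", "generate_hierarchical_dataset", "fixture_smiles"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the two-level cluster generator.

    Default leaf counts (AD 44, SQ 46, SC 35) give the 125-row desk-scale
    dataset; ``n_dims`` can be raised to 1083 to exercise the full
    feature-selection path.
    """

    n_per_leaf: dict = field(default_factory=lambda: {"AD": 44, "SQ": 46, "SC": 35})
    n_dims: int = 200
    n_informative: int = 20
    top_geometry: str = "shells"  # 'linear' | 'shells'
    top_separation: float = 5.0
    sub_separation: float = 3.0
    noise_sd: float = 0.15
    significant_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for leaf in ("AD", "SQ", "SC"):
            if leaf not in self.n_per_leaf:
                raise ValidationError(f"n_per_leaf missing leaf class {leaf!r}")
            if self.n_per_leaf[leaf] < 4:
                raise ValidationError(f"need >= 4 samples per leaf, got {self.n_per_leaf[leaf]} for {leaf}")
        if not (2 <= self.n_informative <= self.n_dims):
            raise ValidationError("n_informative must be in [2, n_dims]")
        if self.top_geometry not in ("linear", "shells"):
            raise ValidationError(f"unknown top_geometry {self.top_geometry!r}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not (0.0 <= self.significant_fraction <= 1.0):
            raise ValidationError("significant_fraction must be in [0, 1]")


def _unit_sphere(rng: np.random.Generator, n: int, d: int) -> np.ndarray:
    v = rng.normal(size=(n, d))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def generate_hierarchical_dataset(spec: SyntheticSpec | None = None) -> tuple[MetaboliteTable, LabeledDataset]:
    """Draw a seeded (table, dataset) pair with the two-level structure.

    Informative dimensions split evenly into a top block (encoding NS vs SC)
    and a sub block (encoding AD vs SQ within NS); everything else is
    Gaussian noise at ``noise_sd``.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)

    leaves: list[str] = []
    for leaf in ("AD", "SQ", "SC"):
        leaves.extend([leaf] * spec.n_per_leaf[leaf])
    n = len(leaves)
    top_dims = spec.n_informative // 2
    sub_dims = spec.n_informative - top_dims

    X = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_dims))
    is_ns = np.array([l in ("AD", "SQ") for l in leaves])
    is_ad = np.array([l == "AD" for l in leaves])

    # top block: NS vs SC
    if spec.top_geometry == "linear":
        shift = spec.top_separation / np.sqrt(top_dims)
        X[:, :top_dims] += np.where(is_ns[:, None], shift, -shift)
    else:
        # concentric shells share their mean, so no linear separator exists
        radii = np.where(is_ns, 1.0, 1.0 + spec.top_separation)
        X[:, :top_dims] += radii[:, None] * _unit_sphere(rng, n, top_dims)

    # sub block: AD vs SQ, only meaningful within NS
    shift = spec.sub_separation / (2.0 * np.sqrt(sub_dims))
    sub = np.zeros((n, sub_dims))
    sub[is_ns & is_ad] = shift
    sub[is_ns & ~is_ad] = -shift
    X[:, top_dims : top_dims + sub_dims] += sub

    names = [f"M{i:04d}" for i in range(n)]
    col_ids = [f"d{j:04d}" for j in range(spec.n_dims)]
    matrix = DescriptorMatrix(names, col_ids, X)

    top_labels = [TopLabel.NS if l in ("AD", "SQ") else TopLabel.SC for l in leaves]
    sub_labels = [SubLabel(l) if l in ("AD", "SQ") else SubLabel.NONE for l in leaves]
    dataset = LabeledDataset(matrix, top_labels, sub_labels)

    significant = rng.random(n) < spec.significant_fraction
    records = []
    for i, name in enumerate(names):
        if significant[i]:
            p = rng.uniform(0.001, 0.05)
            fc = float(np.exp(rng.normal(np.log(1.8), 0.2)))
        else:
            # fail the filter on p, fold change or both
            p = rng.uniform(0.051, 1.0)
            fc = float(np.exp(rng.normal(np.log(1.0), 0.15)))
        records.append(
            MetaboliteRecord(
                name=name,
                p_value=float(p),
                fold_change=fc,
                top_label=top_labels[i],
                sub_label=sub_labels[i],
                smiles=None,
            )
        )
    return MetaboliteTable(records), dataset


#: Real metabolite SMILES used by descriptor-adapter tests; amino-acid
#: biomarkers plus common fatty acids and central-carbon intermediates.
_FIXTURE_SMILES: list[tuple[str, str]] = [
    ("tryptophan", "C1=CC=C2C(=C1)C(=CN2)CC(C(=O)O)N"),
    ("methionine", "CSCCC(C(=O)O)N"),
    ("proline", "C1CC(NC1)C(=O)O"),
    ("alanine", "CC(C(=O)O)N"),
    ("aspartate", "C(C(C(=O)O)N)C(=O)O"),
    ("glutamate", "C(CC(=O)O)C(C(=O)O)N"),
    ("glutamine", "C(CC(=O)N)C(C(=O)O)N"),
    ("glycine", "C(C(=O)O)N"),
    ("serine", "C(C(C(=O)O)N)O"),
    ("cysteine", "C(C(C(=O)O)N)S"),
    ("valine", "CC(C)C(C(=O)O)N"),
    ("glutathione", "C(CC(=O)NC(CS)C(=O)NCC(=O)O)C(C(=O)O)N"),
    ("pantothenate", "CC(C)(CO)C(C(=O)NCCC(=O)O)O"),
    ("taurine", "C(CS(=O)(=O)O)N"),
    ("lactate", "CC(C(=O)O)O"),
    ("pyruvate", "CC(=O)C(=O)O"),
    ("citrate", "C(C(=O)O)C(CC(=O)O)(C(=O)O)O"),
    ("glucose", "C(C1C(C(C(C(O1)O)O)O)O)O"),
    ("palmitic_acid", "CCCCCCCCCCCCCCCC(=O)O"),
    ("stearic_acid", "CCCCCCCCCCCCCCCCCC(=O)O"),
    ("oleic_acid", "CCCCCCCCC=CCCCCCCCC(=O)O"),
    ("linoleic_acid", "CCCCCC=CCC=CCCCCCCCC(=O)O"),
]


def fixture_smiles() -> list[tuple[str, str]]:
    """A fixed list of (name, SMILES) pairs for descriptor-adapter tests."""
    return list(_FIXTURE_SMILES)
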