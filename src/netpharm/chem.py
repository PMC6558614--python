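"""Compound curation and K-means clustering on molecular descriptors.

Curation mirrors the standard database clean-up step: records without a
structure string are removed, and duplicates — identical canonical
structures, or failing that identical case-folded names — are collapsed
keeping the first occurrence.

The default descriptor panel is a compact physicochemical set computable
from the structure alone: molecular weight, heavy-atom count, ring count,
rotatable bonds, H-bond donors/acceptors, topological polar surface area
and fraction of sp3 carbons.  Descriptors are z-scored before clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors
from sklearn.cluster import KMeans

from netpharm.model import Compound, ValidationError

DESCRIPTOR_NAMES = (
    "mol_weight",
    "heavy_atoms",
    "ring_count",
    "rotatable_bonds",
    "hbond_donors",
    "hbond_acceptors",
    "tpsa",
    "fraction_csp3",
)


@dataclass
class DescriptorMatrix:
    """Compounds x descriptors, with a standardization flag."""

    values: pd.DataFrame  # index: compound ids, columns: descriptor names
    standardized: bool = False

    @property
    def compound_ids(self) -> list:
        return list(self.values.index)


def _canonical(smiles: str) -> Optional[str]:
    mol = Chem.MolFromSmiles(smiles)
    return Chem.MolToSmiles(mol) if mol is not None else None


def curate_compounds(raw: Iterable[Compound]) -> list:
    """Remove structure-less and duplicated compounds, keeping first
    occurrences; output order is stable."""
    curated = []
    seen = set()
    for c in raw:
        if not c.smiles:
            continue
        key = _canonical(c.smiles) or c.smiles
        name_key = c.name.casefold()
        if key in seen or name_key in seen:
            continue
        seen.add(key)
        seen.add(name_key)
        curated.append(c)
    return curated


def compute_descriptors(
    compounds: Iterable[Compound],
    precomputed: Optional[pd.DataFrame] = None,
) -> DescriptorMatrix:
    """Compute the default 8-descriptor panel, or accept a user matrix.

    Raises
    ------
    ValidationError
        If a structure string cannot be parsed (the offending compound is
        named), or if a precomputed matrix is missing compounds.
    """
    compounds = list(compounds)
    if precomputed is not None:
        missing = [c.compound_id for c in compounds if c.compound_id not in precomputed.index]
        if missing:
            raise ValidationError(f"precomputed matrix missing compounds: {missing}")
        values = precomputed.loc[[c.compound_id for c in compounds]].astype(float)
        if values.isna().any().any():
            raise ValidationError("precomputed descriptor matrix contains missing values")
        return DescriptorMatrix(values=values, standardized=False)

    rows = []
    for c in compounds:
        if not c.smiles:
            raise ValidationError(f"compound {c.compound_id} has no structure")
        mol = Chem.MolFromSmiles(c.smiles)
        if mol is None:
            raise ValidationError(
                f"compound {c.compound_id}: unparseable structure {c.smiles!r}"
            )
        rows.append(
            [
                Descriptors.MolWt(mol),
                mol.GetNumHeavyAtoms(),
                rdMolDescriptors.CalcNumRings(mol),
                rdMolDescriptors.CalcNumRotatableBonds(mol),
                rdMolDescriptors.CalcNumHBD(mol),
                rdMolDescriptors.CalcNumHBA(mol),
                rdMolDescriptors.CalcTPSA(mol),
                rdMolDescriptors.CalcFractionCSP3(mol),
            ]
        )
    values = pd.DataFrame(
        rows,
        index=[c.compound_id for c in compounds],
        columns=list(DESCRIPTOR_NAMES),
        dtype=float,
    )
    return DescriptorMatrix(values=values, standardized=False)


def standardize(m: DescriptorMatrix) -> DescriptorMatrix:
    """Z-score each column; constant columns are centred but not scaled.

    Applying the function twice changes nothing beyond floating-point
    tolerance.
    """
    v = m.values
    mean = v.mean(axis=0)
    std = v.std(axis=0, ddof=0)
    std = std.where(std > 0, 1.0)
    return DescriptorMatrix(values=(v - mean) / std, standardized=True)


def kmeans_cluster(m: DescriptorMatrix, k: int = 5, seed: int = 0) -> pd.Series:
    """K-means cluster labels (0..k-1) per compound.

    k-means++ initialization with 10 restarts, a 300-iteration cap and a
    1e-6 tolerance; a fixed seed makes labels reproducible.

    Parameters
    ----------
    m
        A standardized descriptor matrix.
    k
        Number of clusters; the customary default for this preparation's
        16-compound panel is 5.
    seed
        Random state for initialization.
    """
    if not m.standardized:
        raise ValidationError("descriptor matrix must be standardized before clustering")
    n = len(m.values)
    if k < 1 or k > n:
        raise ValidationError(f"k={k} outside [1, {n}]")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=10,
        max_iter=300,
        tol=1e-6,
        random_state=seed,
    )
    labels = km.fit_predict(m.values.to_numpy())
    return pd.Series(labels, index=m.values.index, name="cluster")
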