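"""Compound and target descriptors for proteochemometric design matrices.

Compounds are described by *keyed* (unhashed) circular-substructure counts:
every atom environment of radius 0, 1 or 2 bonds (diameter up to four bonds)
occurring in the training set is assigned a stable canonical identifier and a
column of its own, so a model coefficient or attribution score always refers
to a concrete, depictable substructure. Targets are described by concatenating
the five z-scales of the residues at selected binding-site alignment columns.
The two blocks are preprocessed (near-zero-variance filtering, centering and
unit-variance scaling fitted on training rows only) and concatenated row-wise
per (compound, target) datapoint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdmolops
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .bioactivity import BioactivityTable
from .zscales import zscale_vector

__all__ = [
    "SubstructureVocabulary",
    "MorganCountFeaturizer",
    "ZScaleFeaturizer",
    "NearZeroVarianceFilter",
    "CenterScaler",
    "standardize_structures",
    "build_substructure_vocabulary",
    "unhashed_morgan_counts",
    "zscale_descriptors",
    "remove_near_zero_variance",
    "center_scale",
    "assemble_pcm_matrix",
    "read_alignment",
]


# ---------------------------------------------------------------------------
# structure standardization
# ---------------------------------------------------------------------------

def standardize_structures(
    smiles: Sequence[str] | Mapping[str, str],
) -> tuple[dict, dict]:
    """Standardize structures: strip salts/solvents, reject inorganics.

    Multi-fragment inputs are reduced to their largest fragment containing at
    least one carbon atom; inputs with no carbon-bearing fragment are rejected
    as inorganic. No element, halogen-count or molecular-mass restrictions are
    applied. Returns ``(standardized, rejected)`` keyed like the input (by
    index for sequences), with rejected mapping to a reason string.
    """
    if isinstance(smiles, Mapping):
        items = list(smiles.items())
    else:
        items = list(enumerate(smiles))

    standardized: dict = {}
    rejected: dict = {}
    for key, smi in items:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            rejected[key] = "unparseable SMILES"
            continue
        frags = rdmolops.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        organic = [
            f for f in frags
            if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())
        ]
        if not organic:
            rejected[key] = "no organic fragment"
            continue
        best = max(organic, key=lambda f: f.GetNumHeavyAtoms())
        standardized[key] = Chem.MolToSmiles(best)
    return standardized, rejected


# ---------------------------------------------------------------------------
# keyed circular-substructure counts
# ---------------------------------------------------------------------------

@dataclass
class SubstructureVocabulary:
    """Ordered map from circular-environment identifier to column index.

    Identifiers are canonical SMILES of the atom environment rooted at its
    center, prefixed with the radius (e.g. ``"r1|cc(c)c"``), so they are
    portable across runs and platforms rather than being hash integers.
    """

    index: dict[str, int]
    radius: dict[str, int] = field(default_factory=dict)
    example: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.index)

    @property
    def columns(self) -> list[str]:
        return list(self.index)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"index": self.index, "radius": self.radius, "example": self.example},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "SubstructureVocabulary":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = json.loads(text)
        return cls(index=data["index"], radius=data["radius"], example=data["example"])


def _atom_environments(mol: Chem.Mol, max_radius: int) -> list[tuple[int, str]]:
    """Yield (radius, identifier) for every atom's circular environments.

    An atom's environment stops growing once no new bonds are reached; the
    duplicate higher-radius environments are not emitted (standard circular-
    fingerprint behavior), so e.g. ethane has one radius-0 and one radius-1
    environment per carbon and nothing at radius 2.
    """
    out: list[tuple[int, str]] = []
    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        for r in range(max_radius + 1):
            if r == 0:
                frag = Chem.MolFragmentToSmiles(
                    mol, atomsToUse=[idx], bondsToUse=[], canonical=True,
                    allHsExplicit=False, rootedAtAtom=idx,
                )
                out.append((0, f"r0|{frag}"))
                continue
            bonds = Chem.FindAtomEnvironmentOfRadiusN(mol, r, idx)
            if len(bonds) == 0:
                break  # no atoms at exactly this radius: environment exhausted
            atoms = set()
            for b in bonds:
                bond = mol.GetBondWithIdx(b)
                atoms.add(bond.GetBeginAtomIdx())
                atoms.add(bond.GetEndAtomIdx())
            frag = Chem.MolFragmentToSmiles(
                mol, atomsToUse=sorted(atoms), bondsToUse=list(bonds),
                canonical=True, rootedAtAtom=idx,
            )
            out.append((r, f"r{r}|{frag}"))
    return out


class MorganCountFeaturizer(BaseEstimator, TransformerMixin):
    """Keyed circular-substructure count fingerprints.

    ``fit`` enumerates every circular atom environment of radius up to
    ``max_radius`` (default 2, i.e. diameter four bonds) over the training
    molecules and freezes them, sorted by identifier, into a vocabulary.
    ``transform`` counts, per molecule, the atoms whose environment matches
    each vocabulary entry; environments never seen at fit time are silently
    dropped (the keyed array is closed-world).
    """

    def __init__(self, max_radius: int = 2):
        self.max_radius = max_radius

    def fit(self, smiles: Sequence[str], y=None) -> "MorganCountFeaturizer":
        if len(smiles) == 0:
            raise ValueError("cannot build a substructure vocabulary from no molecules")
        radius: dict[str, int] = {}
        example: dict[str, str] = {}
        for smi in smiles:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise ValueError(f"unparseable SMILES {smi!r}")
            for r, env_id in _atom_environments(mol, self.max_radius):
                if env_id not in radius:
                    radius[env_id] = r
                    example[env_id] = smi
        ordered = sorted(radius)
        self.vocabulary_ = SubstructureVocabulary(
            index={env_id: i for i, env_id in enumerate(ordered)},
            radius={env_id: radius[env_id] for env_id in ordered},
            example={env_id: example[env_id] for env_id in ordered},
        )
        return self

    def transform(self, smiles: Sequence[str]) -> pd.DataFrame:
        check_is_fitted(self, "vocabulary_")
        vocab = self.vocabulary_
        mat = np.zeros((len(smiles), len(vocab)), dtype=float)
        for i, smi in enumerate(smiles):
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise ValueError(f"unparseable SMILES {smi!r}")
            for _, env_id in _atom_environments(mol, self.max_radius):
                col = vocab.index.get(env_id)
                if col is not None:
                    mat[i, col] += 1
        return pd.DataFrame(mat, index=list(smiles), columns=vocab.columns)


def build_substructure_vocabulary(
    smiles: Sequence[str], max_radius: int = 2
) -> SubstructureVocabulary:
    """Enumerate all radius-0..max_radius environments over the molecules."""
    return MorganCountFeaturizer(max_radius=max_radius).fit(smiles).vocabulary_


def unhashed_morgan_counts(
    smiles: str | Sequence[str],
    vocab: SubstructureVocabulary,
    max_radius: int = 2,
) -> pd.DataFrame | pd.Series:
    """Count vocabulary substructures in one or more molecules."""
    featurizer = MorganCountFeaturizer(max_radius=max_radius)
    featurizer.vocabulary_ = vocab
    if isinstance(smiles, str):
        return featurizer.transform([smiles]).iloc[0]
    return featurizer.transform(list(smiles))


# ---------------------------------------------------------------------------
# z-scale target descriptors
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path) -> list[tuple[str, str]]:
    """Read an aligned FASTA file into (id, sequence) pairs."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


class ZScaleFeaturizer(BaseEstimator, TransformerMixin):
    """Concatenated z-scales over selected alignment columns.

    ``selected_columns`` is 1-based into the alignment; ``None`` selects all
    positions. Gap characters contribute five zeros. Stateless apart from
    parameter validation, so ``fit`` only records the column selection.
    """

    def __init__(self, selected_columns: Sequence[int] | None = None):
        self.selected_columns = selected_columns

    def fit(self, alignment: Sequence[tuple[str, str]], y=None) -> "ZScaleFeaturizer":
        self.columns_ = (
            list(self.selected_columns)
            if self.selected_columns is not None
            else list(range(1, len(alignment[0][1]) + 1))
        )
        return self

    def transform(self, alignment: Sequence[tuple[str, str]]) -> pd.DataFrame:
        check_is_fitted(self, "columns_")
        lengths = {len(seq) for _, seq in alignment}
        if len(lengths) > 1:
            raise ValueError(f"aligned sequences must share one length, got {sorted(lengths)}")
        (length,) = lengths
        for col in self.columns_:
            if not 1 <= col <= length:
                raise ValueError(f"selected column {col} outside alignment length {length}")
        rows = []
        for seq_id, seq in alignment:
            vec = []
            for col in self.columns_:
                residue = seq[col - 1]
                try:
                    vec.append(zscale_vector(residue))
                except KeyError:
                    raise ValueError(
                        f"non-standard residue {residue!r} in sequence {seq_id!r} "
                        f"at alignment column {col}"
                    ) from None
            rows.append(np.concatenate(vec))
        columns = [f"p{col}_z{k}" for col in self.columns_ for k in range(1, 6)]
        return pd.DataFrame(rows, index=[sid for sid, _ in alignment], columns=columns)


def zscale_descriptors(
    alignment: str | Path | Sequence[tuple[str, str]],
    selected_columns: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Z-scale descriptor block (targets x 5*|columns|) from an alignment."""
    if isinstance(alignment, (str, Path)):
        alignment = read_alignment(alignment)
    featurizer = ZScaleFeaturizer(selected_columns=selected_columns)
    return featurizer.fit(alignment).transform(alignment)


# ---------------------------------------------------------------------------
# design-matrix preprocessing
# ---------------------------------------------------------------------------

class NearZeroVarianceFilter(BaseEstimator, TransformerMixin):
    """Drop constant and near-constant columns.

    A column is removed iff it is constant or the ratio of the frequency of
    its most common value to the frequency of its second most common value is
    strictly greater than ``ratio_cutoff`` (default 30, i.e. a 30/1 cut-off).
    Fitted on training rows only; the mask is reapplied unchanged elsewhere.
    """

    def __init__(self, ratio_cutoff: float = 30.0):
        self.ratio_cutoff = ratio_cutoff

    def fit(self, X: pd.DataFrame | np.ndarray, y=None) -> "NearZeroVarianceFilter":
        X = pd.DataFrame(X)
        mask = []
        for col in X.columns:
            counts = X[col].value_counts().to_numpy()
            if len(counts) < 2:
                mask.append(False)
                continue
            mask.append(not counts[0] / counts[1] > self.ratio_cutoff)
        self.kept_mask_ = np.asarray(mask, dtype=bool)
        self.kept_columns_ = list(X.columns[self.kept_mask_])
        if not self.kept_mask_.any():
            raise ValueError("near-zero-variance filter removed every column")
        return self

    def transform(self, X: pd.DataFrame | np.ndarray) -> pd.DataFrame:
        check_is_fitted(self, "kept_mask_")
        X = pd.DataFrame(X)
        return X.loc[:, X.columns[self.kept_mask_]] if list(X.columns) == list(
            range(X.shape[1])
        ) else X.loc[:, self.kept_columns_]


class CenterScaler(BaseEstimator, TransformerMixin):
    """Center to zero mean, scale to unit variance with the sample SD (n-1).

    Means and SDs are fitted on training rows and applied unchanged to
    held-out rows; a zero training SD raises (it should have been removed by
    the near-zero-variance filter first).
    """

    def fit(self, X: pd.DataFrame | np.ndarray, y=None) -> "CenterScaler":
        X = pd.DataFrame(X)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        zero = self.scale_[self.scale_ == 0]
        if len(zero):
            raise ValueError(f"zero training SD in column(s) {list(zero.index)[:5]}")
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def transform(self, X: pd.DataFrame | np.ndarray) -> pd.DataFrame:
        check_is_fitted(self, "mean_")
        X = pd.DataFrame(X)
        if list(X.columns) == list(range(X.shape[1])):
            X = X.set_axis(self.feature_names_in_, axis=1)
        return (X - self.mean_) / self.scale_


def remove_near_zero_variance(
    block: pd.DataFrame, ratio_cutoff: float = 30.0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Functional wrapper over :class:`NearZeroVarianceFilter` (fit on block)."""
    filt = NearZeroVarianceFilter(ratio_cutoff=ratio_cutoff).fit(block)
    return filt.transform(block), filt.kept_mask_


def center_scale(
    block: pd.DataFrame, fit_rows: Sequence | None = None
) -> tuple[pd.DataFrame, CenterScaler]:
    """Center/scale all rows using statistics fitted on ``fit_rows`` (or all)."""
    fit_block = block.loc[fit_rows] if fit_rows is not None else block
    scaler = CenterScaler().fit(fit_block)
    return scaler.transform(block), scaler


# ---------------------------------------------------------------------------
# PCM design assembly
# ---------------------------------------------------------------------------

def assemble_pcm_matrix(
    compound_block: pd.DataFrame | None,
    target_block: pd.DataFrame | None,
    table: BioactivityTable,
) -> tuple[pd.DataFrame, pd.Series]:
    """Concatenate compound and target descriptors per (compound, target) pair.

    One design row per table entry: ``[compound descriptors | target
    descriptors]``, with the pIC50 response aligned. Passing ``None`` for one
    block yields the family-QSAR (compound only) or family-QSAM (target only)
    ablation design.
    """
    if len(table) == 0:
        raise ValueError("cannot assemble a design matrix from an empty table")
    if compound_block is None and target_block is None:
        raise ValueError("at least one descriptor block is required")

    pairs = list(table.entries)
    blocks = []
    if compound_block is not None:
        missing = {c for c, _ in pairs} - set(compound_block.index)
        if missing:
            raise KeyError(f"no compound descriptor row for {sorted(missing)[:5]}")
        blocks.append(
            compound_block.loc[[c for c, _ in pairs]].reset_index(drop=True)
        )
    if target_block is not None:
        missing = {t for _, t in pairs} - set(target_block.index)
        if missing:
            raise KeyError(f"no target descriptor row for {sorted(missing)[:5]}")
        blocks.append(target_block.loc[[t for _, t in pairs]].reset_index(drop=True))

    design = pd.concat(blocks, axis=1)
    design.index = pd.MultiIndex.from_tuples(pairs, names=["compound_id", "target_id"])
    response = pd.Series(
        [table.entries[p] for p in pairs], index=design.index, name="pIC50"
    )
    return design, response
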