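"""Chemical-novelty profiling of hit compounds.

Similarity to known RNA binders is measured by the Tanimoto coefficient
|A∩B|/|A∪B| over 2048-bit Morgan (circular, radius 2) fingerprints; a
maximum similarity below 0.7 to every reference marks a compound as
dissimilar to the known chemical space.  Physicochemical context comes
from TPSA (Ertl atom-contribution method) and hydrogen-bond donor/acceptor
counts, and chemotype grouping from Bemis–Murcko ring-system frameworks:
compounds share a *scaffold* when their Murcko frameworks match and a
*scaffold class* when the frameworks match after making them generic
(all atoms carbon, all bonds single).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

FINGERPRINT_BITS = 2048
FINGERPRINT_RADIUS = 2
DEFAULT_TANIMOTO_THRESHOLD = 0.7
ACYCLIC_SCAFFOLD = "acyclic"

_fp_generator = rdFingerprintGenerator.GetMorganGenerator(
    radius=FINGERPRINT_RADIUS, fpSize=FINGERPRINT_BITS
)


class SmilesError(ValueError):
    """SMILES string that RDKit cannot parse."""


@dataclass(frozen=True)
class DescriptorSet:
    tpsa: float
    hbd: int
    hba: int

    def __post_init__(self) -> None:
        if self.tpsa < 0 or self.hbd < 0 or self.hba < 0:
            raise ValueError("descriptors must be non-negative")


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    smiles: str
    fingerprint: tuple[int, ...]  # on-bit indices
    descriptors: DescriptorSet
    scaffold_id: str


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"unparseable SMILES: {smiles!r}")
    return mol


def fingerprint(smiles: str) -> np.ndarray:
    """2048-bit Morgan fingerprint as a boolean vector."""
    fp = _fp_generator.GetFingerprint(_mol(smiles))
    bits = np.zeros(FINGERPRINT_BITS, dtype=bool)
    bits[list(fp.GetOnBits())] = True
    return bits


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a∩b| / |a∪b| over equal-length bitsets; 1.0 when both are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 1.0
    return int(np.count_nonzero(a & b)) / union


def descriptors(smiles: str) -> DescriptorSet:
    """TPSA (Ertl contributions) and Lipinski H-bond donor/acceptor counts."""
    mol = _mol(smiles)
    return DescriptorSet(
        tpsa=float(Descriptors.TPSA(mol)),
        hbd=int(Descriptors.NumHDonors(mol)),
        hba=int(Descriptors.NumHAcceptors(mol)),
    )


def scaffold_class(smiles: str, *, generic: bool = False) -> str:
    """Canonical Murcko framework SMILES (generic: carbon skeleton).

    Acyclic molecules map to the sentinel class ``acyclic``.
    """
    mol = _mol(smiles)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold.GetNumAtoms() == 0:
        return ACYCLIC_SCAFFOLD
    if generic:
        scaffold = MurckoScaffold.MakeScaffoldGeneric(scaffold)
    return Chem.MolToSmiles(scaffold)


def group_scaffolds(smiles_list: list[str]) -> tuple[int, int]:
    """(n_scaffolds, n_classes) of a compound set.

    Scaffolds are distinct Murcko frameworks; classes merge frameworks
    that share a generic (carbon-skeleton) ring system.
    """
    scaffolds = {scaffold_class(s) for s in smiles_list}
    classes = {scaffold_class(s, generic=True) for s in smiles_list}
    return len(scaffolds), len(classes)


def compound_record(compound_id: str, smiles: str) -> CompoundRecord:
    return CompoundRecord(
        compound_id=compound_id,
        smiles=smiles,
        fingerprint=tuple(int(i) for i in np.flatnonzero(fingerprint(smiles))),
        descriptors=descriptors(smiles),
        scaffold_id=scaffold_class(smiles),
    )


def novelty_vs_reference(
    smiles: str,
    reference_smiles: list[str],
    threshold: float = DEFAULT_TANIMOTO_THRESHOLD,
) -> tuple[float, float, bool]:
    """(max_sim, mean_sim, dissimilar) of one compound against references.

    Dissimilar ⇔ max similarity strictly below the threshold.
    """
    if not reference_smiles:
        raise ValueError("reference set is empty")
    fp = fingerprint(smiles)
    sims = [tanimoto(fp, fingerprint(r)) for r in reference_smiles]
    max_sim = max(sims)
    return max_sim, float(np.mean(sims)), max_sim < threshold


def novelty_summary(
    hits: dict[str, str],
    references: dict[str, str],
    threshold: float = DEFAULT_TANIMOTO_THRESHOLD,
) -> dict:
    """Per-hit novelty plus mean ± s.d. of per-compound mean similarities."""
    ref_smiles = list(references.values())
    rows = []
    for cid, smi in hits.items():
        max_sim, mean_sim, dissimilar = novelty_vs_reference(smi, ref_smiles, threshold)
        rows.append(
            {
                "compound_id": cid,
                "max_similarity": max_sim,
                "mean_similarity": mean_sim,
                "dissimilar": dissimilar,
            }
        )
    table = pd.DataFrame(rows)
    means = table["mean_similarity"].to_numpy(float)
    return {
        "per_compound": table,
        "mean_tanimoto": float(means.mean()) if len(means) else float("nan"),
        "sd_tanimoto": float(means.std(ddof=1)) if len(means) > 1 else float("nan"),
        "threshold": threshold,
        "fingerprint": f"Morgan r={FINGERPRINT_RADIUS}, {FINGERPRINT_BITS} bits",
    }


def read_smiles(path) -> dict[str, str]:
    """SMILES file: one ``<smiles> <id>`` (or bare SMILES) per line."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for k, line in enumerate(fh):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            smiles = parts[0]
            cid = parts[1] if len(parts) > 1 else f"compound_{k + 1}"
            out[cid] = smiles
    return out


def write_smiles(compounds: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for cid, smi in compounds.items():
            fh.write(f"{smi} {cid}\n")
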