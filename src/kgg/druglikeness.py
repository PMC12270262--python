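"""Physicochemical profiling and the five-filter drug-likeness battery.

Descriptors are computed with RDKit from SMILES; the five boolean gates
(Ghose, Lipinski rule of five, QED, REOS, Veber) are applied on top of the
descriptor vector.  The QED score is an in-house implementation of the
weighted-geometric-mean-of-desirabilities construction (asymmetric double
sigmoid desirability per property, published parameterization); the RDKit
``QED.qed`` value serves only as a frozen regression oracle in the tests.

Hydrogen-bond donors/acceptors follow the original rule-of-five convention:
donors = NH + OH count, acceptors = N + O count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

FILTER_NAMES = ("ghose", "lipinski", "qed", "reos", "veber")

#: Drug types that carry no SMILES and are excluded from profiling.
NO_SMILES_TYPES = {"unknown", "protein", "antibody"}


@dataclass
class MoleculeProfile:
    """Descriptor vector of one molecule."""

    chembl_id: str
    smiles: str
    mw: float
    logp: float
    hbd: int
    hba: int
    tpsa: float
    rotatable_bonds: int
    molar_refractivity: float
    heavy_atoms: int
    total_atoms: int
    formal_charge: int
    aromatic_rings: int
    alert_flags: int = 0
    #: the eight QED input properties (MW, ALOGP, HBA, HBD, PSA, ROTB, AROM,
    #: ALERTS) under the QED definitions, which differ from the rule-of-five
    #: donor/acceptor conventions above.
    qed_properties: Optional[tuple] = None


@dataclass
class FilterResult:
    passed: bool
    violations: list[str] = field(default_factory=list)


@dataclass
class FilterVerdict:
    """Outcome of the full battery for one molecule."""

    chembl_id: str
    passes: dict[str, bool]
    qed_score: float
    violations: dict[str, list[str]]

    @property
    def pass_all(self) -> bool:
        return all(self.passes[n] for n in FILTER_NAMES)

    @property
    def pass_none(self) -> bool:
        return not any(self.passes[n] for n in FILTER_NAMES)


class SmilesParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# descriptor computation (RDKit-backed)
# ---------------------------------------------------------------------------

def compute_profile(smiles: str, chembl_id: str = "") -> MoleculeProfile:
    """Compute the descriptor vector for a SMILES string.

    Raises :class:`SmilesParseError` for unparseable input; callers batching
    molecules should collect these as per-molecule error records.
    """
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, Lipinski, QED, rdMolDescriptors

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES for {chembl_id or '<molecule>'}: {smiles!r}")
    molh = Chem.AddHs(mol)
    qprops = QED.properties(mol)
    return MoleculeProfile(
        chembl_id=chembl_id,
        smiles=smiles,
        mw=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        hbd=Lipinski.NHOHCount(mol),
        hba=Lipinski.NOCount(mol),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        rotatable_bonds=rdMolDescriptors.CalcNumRotatableBonds(mol),
        molar_refractivity=Crippen.MolMR(mol),
        heavy_atoms=mol.GetNumHeavyAtoms(),
        total_atoms=molh.GetNumAtoms(),
        formal_charge=Chem.GetFormalCharge(mol),
        aromatic_rings=rdMolDescriptors.CalcNumAromaticRings(mol),
        alert_flags=int(qprops.ALERTS),
        qed_properties=tuple(qprops),
    )


# ---------------------------------------------------------------------------
# the five gates (all range bounds inclusive)
# ---------------------------------------------------------------------------

def lipinski(p: MoleculeProfile, max_violations: int = 0) -> FilterResult:
    """Rule of five: MW <= 500, logP <= 5, HBD <= 5, HBA <= 10.

    Default is the strict zero-violation form; ``max_violations=1`` recovers
    the classical allowance.
    """
    checks = {
        "mw": p.mw <= 500.0,
        "logp": p.logp <= 5.0,
        "hbd": p.hbd <= 5,
        "hba": p.hba <= 10,
    }
    violations = [k for k, ok in checks.items() if not ok]
    return FilterResult(len(violations) <= max_violations, violations)


def ghose(p: MoleculeProfile) -> FilterResult:
    checks = {
        "mw": 160.0 <= p.mw <= 480.0,
        "logp": -0.4 <= p.logp <= 5.6,
        "molar_refractivity": 40.0 <= p.molar_refractivity <= 130.0,
        "total_atoms": 20 <= p.total_atoms <= 70,
    }
    violations = [k for k, ok in checks.items() if not ok]
    return FilterResult(not violations, violations)


def veber(p: MoleculeProfile) -> FilterResult:
    checks = {
        "rotatable_bonds": p.rotatable_bonds <= 10,
        "tpsa": p.tpsa <= 140.0,
    }
    violations = [k for k, ok in checks.items() if not ok]
    return FilterResult(not violations, violations)


def reos(p: MoleculeProfile, use_alerts: bool = False) -> FilterResult:
    """Numeric-bounds REOS; structural-alert rejection is opt-in."""
    checks = {
        "mw": 200.0 <= p.mw <= 500.0,
        "logp": -5.0 <= p.logp <= 5.0,
        "hbd": p.hbd <= 5,
        "hba": p.hba <= 10,
        "formal_charge": -2 <= p.formal_charge <= 2,
        "rotatable_bonds": p.rotatable_bonds <= 8,
        "heavy_atoms": 15 <= p.heavy_atoms <= 50,
    }
    if use_alerts:
        checks["alerts"] = p.alert_flags == 0
    violations = [k for k, ok in checks.items() if not ok]
    return FilterResult(not violations, violations)


# -- QED --------------------------------------------------------------------

#: Asymmetric double sigmoid parameters (A, B, C, D, E, F, DMAX) per property,
#: as published with the original QED method.
_ADS_PARAMS: dict[str, tuple[float, ...]] = {
    "MW": (2.817065973, 392.5754953, 290.7489764, 2.419764353, 49.22325677, 65.37051707, 104.9805561),
    "ALOGP": (3.172690585, 137.8624751, 2.534937431, 4.581497897, 0.822739154, 0.576295591, 131.3186604),
    "HBA": (2.948620388, 160.4605972, 3.615294657, 4.435986202, 0.290141953, 1.300669958, 148.7763046),
    "HBD": (1.618662227, 1010.051101, 0.985094388, 0.000000001, 0.713820843, 0.920922555, 258.1632616),
    "PSA": (1.876861559, 125.2232657, 62.90773554, 87.83366614, 12.01999824, 28.51324732, 104.5686167),
    "ROTB": (0.010000000, 272.4121427, 2.558379970, 1.565547684, 1.271567166, 2.758063707, 105.4420403),
    "AROM": (3.217788970, 957.7374108, 2.274627939, 0.000000001, 1.317690384, 0.375760881, 312.3372610),
    "ALERTS": (0.010000000, 1199.094025, -0.09002883, 0.000000001, 0.185904477, 0.875193782, 417.7253140),
}

#: Unweighted-mean weights of the original method (the default weighting).
_QED_WEIGHTS: dict[str, float] = {
    "MW": 0.66, "ALOGP": 0.46, "HBA": 0.05, "HBD": 0.61,
    "PSA": 0.06, "ROTB": 0.65, "AROM": 0.48, "ALERTS": 0.95,
}

_QED_ORDER = ("MW", "ALOGP", "HBA", "HBD", "PSA", "ROTB", "AROM", "ALERTS")


def _desirability(x: float, params: tuple[float, ...]) -> float:
    a, b, c, d, e, f, dmax = params
    left = 1.0 + math.exp(-(x - c + d / 2.0) / e)
    right = 1.0 + math.exp(-(x - c - d / 2.0) / f)
    return (a + b / left * (1.0 - 1.0 / right)) / dmax


def qed_score(p: MoleculeProfile) -> float:
    """Weighted geometric mean of the eight property desirabilities, in [0,1]."""
    if p.qed_properties is None:
        raise ValueError("profile lacks the QED property vector; use compute_profile")
    total_w = 0.0
    acc = 0.0
    for name, value in zip(_QED_ORDER, p.qed_properties):
        w = _QED_WEIGHTS[name]
        d = max(_desirability(float(value), _ADS_PARAMS[name]), 1e-10)
        acc += w * math.log(d)
        total_w += w
    return math.exp(acc / total_w)


def qed(p: MoleculeProfile, threshold: float = 0.5) -> FilterResult:
    score = qed_score(p)
    ok = score >= threshold
    return FilterResult(ok, [] if ok else [f"qed_score {score:.3f} < {threshold}"])


# ---------------------------------------------------------------------------
# battery
# ---------------------------------------------------------------------------

def evaluate(p: MoleculeProfile, qed_threshold: float = 0.5,
             lipinski_max_violations: int = 0, reos_alerts: bool = False) -> FilterVerdict:
    results = {
        "ghose": ghose(p),
        "lipinski": lipinski(p, max_violations=lipinski_max_violations),
        "qed": qed(p, threshold=qed_threshold),
        "reos": reos(p, use_alerts=reos_alerts),
        "veber": veber(p),
    }
    return FilterVerdict(
        chembl_id=p.chembl_id,
        passes={name: r.passed for name, r in results.items()},
        qed_score=qed_score(p),
        violations={name: r.violations for name, r in results.items()},
    )


@dataclass
class DruglikenessReport:
    """Battery outcome for a drug list, with the tallies the analyses need."""

    table: pd.DataFrame                 # one row per profiled drug
    dropped: pd.DataFrame               # drug id, reason
    per_filter_counts: dict[str, int]
    pass_all_count: int
    pass_none_count: int
    pass_all_by_phase: dict[int, int]
    pass_none_by_phase: dict[int, int]
    long_table: pd.DataFrame            # long format for parallel coordinates

    @property
    def n_evaluated(self) -> int:
        return len(self.table)


def _report_from_rows(rows: list[dict], dropped: list[dict]) -> DruglikenessReport:
    table = pd.DataFrame(rows)
    if table.empty:
        table = pd.DataFrame(columns=["chembl_id", "name", "drug_type", "max_phase",
                                      "qed_score", *FILTER_NAMES, "pass_all", "pass_none"])
    per_filter = {name: int(table[name].sum()) if name in table else 0 for name in FILTER_NAMES}
    pass_all = int(table["pass_all"].sum()) if "pass_all" in table and len(table) else 0
    pass_none = int(table["pass_none"].sum()) if "pass_none" in table and len(table) else 0

    def _by_phase(col: str) -> dict[int, int]:
        out: dict[int, int] = {}
        if len(table) and col in table:
            sub = table[table[col]]
            for phase, n in sub.groupby("max_phase", dropna=False).size().items():
                key = -1 if pd.isna(phase) else int(phase)
                out[key] = int(n)
        return out

    descriptor_cols = [c for c in ("mw", "logp", "hbd", "hba", "tpsa",
                                   "rotatable_bonds", "molar_refractivity",
                                   "heavy_atoms", "qed_score") if c in table]
    if len(table):
        long_table = table.melt(id_vars=["chembl_id"], value_vars=descriptor_cols,
                                var_name="property", value_name="value")
    else:
        long_table = pd.DataFrame(columns=["chembl_id", "property", "value"])

    return DruglikenessReport(
        table=table,
        dropped=pd.DataFrame(dropped, columns=["chembl_id", "drug_type", "reason"]),
        per_filter_counts=per_filter,
        pass_all_count=pass_all,
        pass_none_count=pass_none,
        pass_all_by_phase=_by_phase("pass_all"),
        pass_none_by_phase=_by_phase("pass_none"),
        long_table=long_table,
    )


def druglikeness_table(drugs: Iterable, qed_threshold: float = 0.5,
                       lipinski_max_violations: int = 0,
                       reos_alerts: bool = False) -> DruglikenessReport:
    """Run the battery over DrugRecord-like objects.

    Drugs whose type is unknown/protein/antibody, or whose SMILES is absent or
    unparseable, are dropped with a logged reason and reported in ``dropped``.
    """
    rows: list[dict] = []
    dropped: list[dict] = []
    for drug in drugs:
        dtype = (getattr(drug, "drug_type", "") or "").strip().lower()
        if dtype in NO_SMILES_TYPES:
            dropped.append({"chembl_id": drug.chembl_id, "drug_type": dtype,
                            "reason": "drug type without SMILES"})
            continue
        if not getattr(drug, "smiles", None):
            dropped.append({"chembl_id": drug.chembl_id, "drug_type": dtype,
                            "reason": "missing SMILES"})
            continue
        try:
            profile = compute_profile(drug.smiles, chembl_id=drug.chembl_id)
        except SmilesParseError as exc:
            dropped.append({"chembl_id": drug.chembl_id, "drug_type": dtype,
                            "reason": f"parse error: {exc}"})
            continue
        verdict = evaluate(profile, qed_threshold=qed_threshold,
                           lipinski_max_violations=lipinski_max_violations,
                           reos_alerts=reos_alerts)
        rows.append({
            "chembl_id": drug.chembl_id,
            "name": getattr(drug, "preferred_name", ""),
            "drug_type": dtype,
            "max_phase": getattr(drug, "max_phase", None),
            "mw": profile.mw, "logp": profile.logp, "hbd": profile.hbd,
            "hba": profile.hba, "tpsa": profile.tpsa,
            "rotatable_bonds": profile.rotatable_bonds,
            "molar_refractivity": profile.molar_refractivity,
            "heavy_atoms": profile.heavy_atoms,
            "qed_score": verdict.qed_score,
            **verdict.passes,
            "pass_all": verdict.pass_all,
            "pass_none": verdict.pass_none,
        })
    for d in dropped:
        logger.info("druglikeness: dropped %s (%s)", d["chembl_id"], d["reason"])
    return _report_from_rows(rows, dropped)


# ---------------------------------------------------------------------------
# battery over precomputed property tables
# ---------------------------------------------------------------------------

_TABLE_COLUMN_ALIASES = {
    "chembl_id": ("chembl_id", "molecule_chembl_id", "id"),
    "name": ("name", "preferred_name", "pref_name", "drug"),
    "drug_type": ("drug_type", "type"),
    "max_phase": ("max_phase", "phase", "clinical_phase", "highest_phase"),
    "smiles": ("smiles", "canonical_smiles"),
    "mw": ("mw", "molecular_weight", "molwt", "full_mwt"),
    "logp": ("logp", "alogp", "clogp", "slogp"),
    "hbd": ("hbd", "num_hbd", "hbds", "h_bond_donor"),
    "hba": ("hba", "num_hba", "hbas", "h_bond_acceptor"),
    "tpsa": ("tpsa", "psa", "polar_surface_area"),
    "rotatable_bonds": ("rotatable_bonds", "num_rotatable_bonds", "rtb", "rotb"),
    "molar_refractivity": ("molar_refractivity", "mr", "refractivity"),
    "heavy_atoms": ("heavy_atoms", "num_heavy_atoms", "heavy_atom_count"),
    "total_atoms": ("total_atoms", "num_atoms", "atom_count"),
    "formal_charge": ("formal_charge", "charge"),
    "aromatic_rings": ("aromatic_rings", "num_aromatic_rings", "arom"),
    "qed_score": ("qed_score", "qed", "qed_weighted"),
}


def load_property_table(path) -> pd.DataFrame:
    """Load a per-drug physicochemical property table (CSV/TSV/XLSX).

    Column names are normalized through a tolerant alias map so tables
    exported by different tools can be fed to :func:`battery_from_table`.
    """
    path = str(path)
    if path.endswith((".xlsx", ".xls")):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep=None, engine="python")
    lower = {c.lower().strip().replace(" ", "_"): c for c in df.columns}
    rename = {}
    for canon, aliases in _TABLE_COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                rename[lower[alias]] = canon
                break
    return df.rename(columns=rename)


def battery_from_table(df: pd.DataFrame, qed_threshold: float = 0.5,
                       lipinski_max_violations: int = 0) -> DruglikenessReport:
    """Apply the five gates to a precomputed property table.

    Missing descriptor columns are recomputed from a ``smiles`` column when
    present; a table lacking both is rejected.  Rows with drug type
    unknown/protein/antibody or without usable descriptors are dropped with
    reasons, mirroring :func:`druglikeness_table`.
    """
    numeric = ("mw", "logp", "hbd", "hba", "tpsa", "rotatable_bonds",
               "molar_refractivity", "heavy_atoms", "total_atoms",
               "formal_charge", "aromatic_rings")
    rows: list[dict] = []
    dropped: list[dict] = []
    for _, rec in df.iterrows():
        cid = str(rec.get("chembl_id", rec.get("name", "")))
        dtype = str(rec.get("drug_type", "")).strip().lower()
        if dtype in NO_SMILES_TYPES:
            dropped.append({"chembl_id": cid, "drug_type": dtype,
                            "reason": "drug type without SMILES"})
            continue
        have_all = all(c in rec.index and pd.notna(rec.get(c)) for c in numeric)
        have_qed = "qed_score" in rec.index and pd.notna(rec.get("qed_score"))
        if have_all and have_qed:
            profile = MoleculeProfile(
                chembl_id=cid, smiles=str(rec.get("smiles", "")),
                mw=float(rec["mw"]), logp=float(rec["logp"]),
                hbd=int(rec["hbd"]), hba=int(rec["hba"]), tpsa=float(rec["tpsa"]),
                rotatable_bonds=int(rec["rotatable_bonds"]),
                molar_refractivity=float(rec["molar_refractivity"]),
                heavy_atoms=int(rec["heavy_atoms"]), total_atoms=int(rec["total_atoms"]),
                formal_charge=int(rec["formal_charge"]),
                aromatic_rings=int(rec["aromatic_rings"]))
            score = float(rec["qed_score"])
        elif isinstance(rec.get("smiles"), str) and rec.get("smiles"):
            try:
                profile = compute_profile(rec["smiles"], chembl_id=cid)
            except SmilesParseError as exc:
                dropped.append({"chembl_id": cid, "drug_type": dtype,
                                "reason": f"parse error: {exc}"})
                continue
            score = qed_score(profile)
        else:
            dropped.append({"chembl_id": cid, "drug_type": dtype,
                            "reason": "incomplete descriptors and no SMILES"})
            continue
        passes = {
            "ghose": ghose(profile).passed,
            "lipinski": lipinski(profile, max_violations=lipinski_max_violations).passed,
            "qed": score >= qed_threshold,
            "reos": reos(profile).passed,
            "veber": veber(profile).passed,
        }
        phase = rec.get("max_phase")
        rows.append({
            "chembl_id": cid, "name": str(rec.get("name", "")), "drug_type": dtype,
            "max_phase": None if pd.isna(phase) else int(phase),
            "mw": profile.mw, "logp": profile.logp, "hbd": profile.hbd,
            "hba": profile.hba, "tpsa": profile.tpsa,
            "rotatable_bonds": profile.rotatable_bonds,
            "molar_refractivity": profile.molar_refractivity,
            "heavy_atoms": profile.heavy_atoms,
            "qed_score": score,
            **passes,
            "pass_all": all(passes.values()),
            "pass_none": not any(passes.values()),
        })
    return _report_from_rows(rows, dropped)
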