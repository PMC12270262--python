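"""One-off: freeze descriptor/QED oracle columns for bundled drug SMILES."""
import csv
import pathlib
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, QED, rdMolDescriptors

DRUGS = [
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1"),
    ("ibuprofen", "CC(C)Cc1ccc(C(C)C(=O)O)cc1"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("levodopa", "N[C@@H](Cc1ccc(O)c(O)c1)C(=O)O"),
    ("carbidopa", "C[C@@](Cc1ccc(O)c(O)c1)(C(=O)O)NN"),
    ("pramipexole", "CCCN[C@H]1CCc2nc(N)sc2C1"),
    ("ropinirole", "CCCN(CCC)CCc1cccc2c1CC(=O)N2"),
    ("rasagiline", "C#CCN[C@H]1CCc2ccccc21"),
    ("selegiline", "C#CCN(C)[C@@H](C)Cc1ccccc1"),
    ("entacapone", "CCN(CC)C(=O)/C(C#N)=C/c1cc(O)c(O)c([N+](=O)[O-])c1"),
    ("tolcapone", "Cc1ccc(C(=O)c2cc(O)c(O)c([N+](=O)[O-])c2)cc1"),
    ("amantadine", "NC12CC3CC(CC(C3)C1)C2"),
    ("apomorphine", "CN1CCc2cccc3c2[C@H]1Cc1ccc(O)c(O)c1-3"),
    ("benserazide", "NC(CO)C(=O)NNCc1cc(O)c(O)c(O)c1"),
    ("bromocriptine", "CC(C)C[C@H]1C(=O)N2CCC[C@H]2[C@]2(O)O[C@](NC(=O)[C@@H]3C=C4c5cccc6[nH]c(Br)c(c56)C[C@H]4N(C)C3)(C(C)C)C(=O)N12"),
    ("istradefylline", "CCn1c(=O)c2c(nc(/C=C/c3ccc(OC)c(OC)c3)n2C)n(CC)c1=O"),
    ("safinamide", "C[C@H](NCc1ccc(OCc2cccc(F)c2)cc1)C(N)=O"),
    ("trihexyphenidyl", "OC(CCN1CCCCC1)(c1ccccc1)C1CCCCC1"),
    ("biperiden", "OC(CCN1CCCCC1)(c1ccccc1)C1CC2C=CC1C2"),
    ("donepezil", "COc1cc2c(cc1OC)C(=O)C(CC1CCN(Cc3ccccc3)CC1)C2"),
    ("memantine", "CC12CC3CC(C)(C1)CC(N)(C3)C2"),
    ("rivastigmine", "CCN(C)C(=O)Oc1cccc([C@H](C)N(C)C)c1"),
    ("galantamine", "COc1ccc2c3c1O[C@H]1C[C@@H](O)C=C[C@@]31CCN(C)C2"),
    ("fluoxetine", "CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1"),
    ("sertraline", "CN[C@H]1CC[C@@H](c2ccc(Cl)c(Cl)c2)c2ccccc21"),
    ("citalopram", "CN(C)CCCC1(c2ccc(F)cc2)OCc2cc(C#N)ccc21"),
    ("venlafaxine", "COc1ccc(C(CN(C)C)C2(O)CCCCC2)cc1"),
    ("bupropion", "CC(NC(C)(C)C)C(=O)c1cccc(Cl)c1"),
    ("duloxetine", "CNCC[C@@H](Oc1cccc2ccccc12)c1cccs1"),
    ("mirtazapine", "CN1CCN2c3ccccc3Cc3ccccc3C2C1"),
    ("trazodone", "O=c1n(CCCN2CCN(c3cccc(Cl)c3)CC2)nc2ccccn12"),
    ("amitriptyline", "CN(C)CCC=C1c2ccccc2CCc2ccccc21"),
    ("imipramine", "CN(C)CCCN1c2ccccc2CCc2ccccc21"),
    ("quetiapine", "OCCOCCN1CCN(C2=Nc3ccccc3Sc3ccccc32)CC1"),
    ("olanzapine", "Cc1cc2c(s1)Nc1ccccc1N=C2N1CCN(C)CC1"),
    ("risperidone", "Cc1nc2n(c1CCN1CCC(c3noc4cc(F)ccc34)CC1)CCCC2=O"),
    ("aripiprazole", "O=C1CCc2ccc(OCCCCN3CCN(c4cccc(Cl)c4Cl)CC3)cc2N1"),
    ("haloperidol", "O=C(CCCN1CCC(O)(c2ccc(Cl)cc2)CC1)c1ccc(F)cc1"),
    ("clozapine", "CN1CCN(C2=Nc3cc(Cl)ccc3Nc3ccccc32)CC1"),
    ("tetrabenazine", "COc1cc2c(cc1OC)C1CC(C(=O)C2)C(CC(C)C)CN1C"),
    ("metformin", "CN(C)C(=N)NC(=N)N"),
    ("atorvastatin", "CC(C)c1c(C(=O)Nc2ccccc2)c(-c2ccccc2)c(-c2ccc(F)cc2)n1CC[C@@H](O)C[C@@H](O)CC(=O)O"),
    ("warfarin", "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O"),
    ("lisinopril", "NCCCC[C@H](N[C@@H](CCc1ccccc1)C(=O)O)C(=O)N1CCC[C@H]1C(=O)O"),
    ("omeprazole", "CC1=CN=C(C(=C1OC)C)CS(=O)C2=NC3=CC=C(C=C3N2)OC"),
    ("simvastatin", "CCC(C)(C)C(=O)O[C@H]1C[C@@H](C)C=C2C=C[C@H](C)[C@H](CC[C@@H]3C[C@@H](O)CC(=O)O3)[C@@H]21"),
    ("propranolol", "CC(C)NCC(O)COc1cccc2ccccc12"),
    ("atenolol", "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1"),
    ("ethanol", "CCO"),
    ("nicotine", "CN1CCC[C@H]1c1cccnc1"),
    ("morphine", "CN1CC[C@]23c4c5ccc(O)c4O[C@H]2[C@@H](O)C=C[C@H]3[C@H]1C5"),
    ("penicillin-g", "CC1(C)S[C@@H]2[C@H](NC(=O)Cc3ccccc3)C(=O)N2[C@H]1C(=O)O"),
    ("doxycycline", "C[C@@H]1c2cccc(O)c2C(=O)C2=C(O)[C@]3(O)C(=O)C(C(N)=O)=C(O)[C@@H](N(C)C)[C@@H]3[C@@H](O)[C@H]21"),
]

rows = []
for name, smi in DRUGS:
    mol = Chem.MolFromSmiles(smi)
    if mol is None:
        print("BAD SMILES:", name)
        continue
    molh = Chem.AddHs(mol)
    props = QED.properties(mol)
    rows.append({
        "name": name,
        "smiles": Chem.MolToSmiles(mol),
        "mw": round(Descriptors.MolWt(mol), 4),
        "logp": round(Crippen.MolLogP(mol), 4),
        "hbd": Lipinski.NHOHCount(mol),
        "hba": Lipinski.NOCount(mol),
        "tpsa": round(rdMolDescriptors.CalcTPSA(mol), 4),
        "rotatable_bonds": rdMolDescriptors.CalcNumRotatableBonds(mol),
        "molar_refractivity": round(Crippen.MolMR(mol), 4),
        "heavy_atoms": mol.GetNumHeavyAtoms(),
        "total_atoms": molh.GetNumAtoms(),
        "formal_charge": Chem.GetFormalCharge(mol),
        "aromatic_rings": rdMolDescriptors.CalcNumAromaticRings(mol),
        "qed_mw": round(props.MW, 6), "qed_alogp": round(props.ALOGP, 6),
        "qed_hba": props.HBA, "qed_hbd": props.HBD,
        "qed_psa": round(props.PSA, 6), "qed_rotb": props.ROTB,
        "qed_arom": props.AROM, "qed_alerts": props.ALERTS,
        "qed_ref": round(QED.qed(mol), 6),
    })

out = pathlib.Path(__file__).resolve().parents[1] / "src/kgg/sources/data/reference_molecules.csv"
with open(out, "w", newline="") as fh:
    w = csv.DictWriter(fh, fieldnames=list(rows[0]))
    w.writeheader()
    w.writerows(rows)
print("wrote", len(rows), "molecules")
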