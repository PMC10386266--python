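"""Effective intestinal permeability of the six reference drug products.

Evaluates the halogen-corrected power law Peff = 265.8 * MW_eff^-4.5 * MA
(MA = 10^logP, cm/s, reported in cm/min) for each reference molecule; drugs
with a measured-permeability override (nimodipine, from a Caco-2 assay)
bypass the correlation.
"""

from biphasepk import REFERENCE_DRUGS, effective_mw, peff, peff_cm_s

print(f"{'drug':<16}{'MW':>8}{'MW_eff':>9}{'logP':>6}{'Peff cm/min':>13}{'Peff cm/s':>12}")
for name, mol in REFERENCE_DRUGS.items():
    mw_eff = effective_mw(mol)
    tag = "*" if mol.peff_override is not None else " "
    print(f"{name:<16}{mol.mw:>8.2f}{mw_eff:>9.2f}"
          f"{(mol.logp if mol.logp is not None else float('nan')):>6.1f}"
          f"{peff(mol):>12.2e}{tag}{peff_cm_s(mol):>12.2e}")
print("\n* measured-permeability override (Caco-2 derived), correlation bypassed")
print("Higher lipophilicity raises Peff 10x per logP unit; halogen-corrected")
print("mass lowers it with the -4.5 power.")
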