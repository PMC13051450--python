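"""Simulate and fit a two-site ITC titration.

Forward-models injection heats for a titration with a high-affinity
specific site class (n = 2.5, Kd = 121 nM) and a low-affinity nonspecific
class (n = 18, Kd = 1.92 uM), adds 2% Gaussian noise, fits both the one-
and two-site independent-sites models, and lets an F-test choose.
"""

from coassembler.affinity import dG_from_Kd
from coassembler.fixtures import ITCSpec, simulate_itc
from coassembler.itc import fit_isotherm, select_model

spec = ITCSpec(seed=42)
isotherm = simulate_itc(spec)
print(f"simulated {len(isotherm.heats)} injections, molar ratio "
      f"{isotherm.molar_ratio[0]:.1f} to {isotherm.molar_ratio[-1]:.1f}")

setup = dict(cell_volume=spec.cell_volume, cell_conc=spec.cell_conc,
             syringe_conc=spec.syringe_conc)
fit_one = fit_isotherm(isotherm, "one_site", **setup)
fit_two = fit_isotherm(isotherm, "two_site", **setup)
label, f_stat = select_model(fit_one, fit_two)
print(f"model selection: {label} (F = {f_stat:.1f}; "
      f"RSS one-site {fit_one.rss:.3g} vs two-site {fit_two.rss:.3g})")
# A large F means the second site class reduces the residual error far more
# than two extra parameters would by chance.

high, low = fit_two.sites
print(f"high-affinity site: n = {high.n:.2f}, Kd = {high.Kd * 1e9:.0f} nM, "
      f"ΔH = {high.dH:.1f} kcal/mol, ΔG = {dG_from_Kd(high.Kd):.2f} kcal/mol")
print(f"low-affinity site:  n = {low.n:.1f}, Kd = {low.Kd * 1e6:.2f} uM, "
      f"ΔH = {low.dH:.1f} kcal/mol, ΔG = {dG_from_Kd(low.Kd):.2f} kcal/mol")
# Stoichiometries are recovered tightly; the high-affinity Kd carries the
# widest uncertainty because the 25-injection schedule crosses its steep
# binding transition in only a couple of points.
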