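"""Build the three plant carbon input components for a grazed sward.

Above-ground residue is 20 % of standing above-ground carbon; below-ground
biomass follows from the N-dependent root:shoot ratio, half of it turning
over each year; rhizodeposition adds another half of root carbon as fully
labile input.  Note how much of the total enters below ground -- the part
the classic lumped treatment under-counts.
"""

import numpy as np

from rothc_grass import (
    PlantResidueSpec,
    annual_components,
    distribute_monthly,
    root_shoot_ratio,
)

spec = PlantResidueSpec(above_ground_biomass=10.0, management="grazed", n_input=214.0)
rs = root_shoot_ratio(spec.n_input)
c = annual_components(spec)
print(f"10 Mg DM standing biomass, 214 kg N/ha/yr -> R:S = {rs:.2f}")
print(f"  above-ground residue C : {c['c_above']:.2f} Mg C/ha/yr")
print(f"  below-ground residue C : {c['c_below']:.2f} Mg C/ha/yr")
print(f"  rhizodeposition C      : {c['c_rhizo']:.2f} Mg C/ha/yr")
print(f"  total                  : {sum(c.values()):.2f} Mg C/ha/yr")

# seasonal fibre increase: residues lignify as the season advances
ndf = np.linspace(30.0, 70.0, 12)
monthly = distribute_monthly(c, ndf_by_month=ndf)
print("\nmonth  plant C   DPM share of above-ground residue")
for m in (4, 7, 10):
    print(
        f"  {m + 1:2d}   {monthly.total_plant_c(m):5.2f}      "
        f"{monthly.f_dpm_above[m]:.2f}"
    )
print("late-season residue is more fibrous, so less of it enters the fast pool")
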