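# Packaged data

`photon_xsections.csv` — photon interaction data for the six transport
materials (air, lung, soft tissue, bone, water, copper), 5–150 keV.

Columns:

| column       | meaning                                                     |
|--------------|-------------------------------------------------------------|
| `material`   | material name                                               |
| `energy_keV` | grid energy (keV); copper carries two close-lying points at |
|              | its K edge (8.979 keV)                                      |
| `mu_rho`     | mass attenuation coefficient μ/ρ, cm²/g                     |
| `mutr_rho`   | mass energy-transfer coefficient μ_tr/ρ, cm²/g (taken equal |
|              | to the energy-absorption coefficient; radiative losses are  |
|              | negligible below 150 keV)                                   |
| `f_pe`,`f_co`,`f_ra` | photoelectric / Compton / Rayleigh fractions of the |
|              | total cross section; sum to 1 at every row                  |

Provenance: μ/ρ and μ_tr/ρ anchors are transcribed at round energies from the
standard NIST XCOM element/compound tables and the ICRU Report 44 tissue
compilations. The channel fractions are derived from those totals: the Compton
fraction from the closed-form total Klein–Nishina cross section times the
material's electron density (Z/A), the Rayleigh fraction from a per-material
power-law coherent-scatter model calibrated near 30 keV, and the
photoelectric fraction as the remainder, with the triple renormalized to sum
to exactly 1. Between grid points all quantities are log-log interpolated.
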