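"""Spectral signatures: emission grids, concatenation, species means.

Each load is measured at six excitation wavelengths; each emission grid starts
50 nm above its excitation and ends at 740 nm, so the concatenated signature
has 326 + 301 + 296 + 231 + 161 + 66 = 1381 named features.
"""

import numpy as np

import pollensig as ps
from pollensig.signature import species_mean

for exc in ps.EXCITATION_WAVELENGTHS:
    g = ps.emission_grid(exc)
    print(f"excitation {exc} nm -> emission {g[0]}-{g[-1]} nm ({len(g)} features)")
print(f"total spectroscopy features: {ps.N_SPECTRO_FEATURES}")

sim = ps.make_dataset(ps.SimConfig(seed=1, n_species=3, loads_per_species=10, n_dropped=0))
record = sim.spectroscopy.records[0]
signature = ps.concatenate_signature(record)
print(f"\nload {record.load_id} ({record.species}, tone {record.tone})")
print(f"first feature {signature.names[0]} = {signature.values[0]:.2f}, "
      f"last {signature.names[-1]} = {signature.values[-1]:.2f}")

# Per-species mean and dispersion over loads; the intensity scale varies a lot
# between loads (brightness), the peak positions do not.
sig = species_mean(sim.spectroscopy, record.species)
peak = int(np.argmax(sig.mean))
print(f"species mean over n={sig.n} loads peaks at {sig.names[peak]} "
      f"(mean {sig.mean[peak]:.1f}, sd {sig.sd[peak]:.1f})")

# Max-normalisation rescales each spectrum to peak 1 for shape comparison.
norm = ps.max_normalize(record.spectra[365])
print(f"normalised 365 nm spectrum: max {norm.intensities.max():.1f}, "
      f"shape preserved (argmax unchanged: "
      f"{np.argmax(norm.intensities) == np.argmax(record.spectra[365].intensities)})")
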