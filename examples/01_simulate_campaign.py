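"""Generate a synthetic pollen-load campaign and write its tables.

Builds 14 species models (mixtures of Gaussian emission bands), samples two
dozen loads per species, and serialises both measurement modalities: the long
spectra table (six emission grids per load) and the 18-feature analyser table.
"""

from pathlib import Path

import pollensig as ps
from pollensig import io

out = Path("scratch/example_campaign")
out.mkdir(parents=True, exist_ok=True)

config = ps.SimConfig(seed=1)  # 14 species x 24 loads, 3 spectroscopy drops
sim = ps.make_dataset(config)

io.write_spectra_table(sim.spectroscopy, out / "spectra.csv")
io.write_feature_table(sim.analyser, out / "features.csv")
sim.truth.sort_values("load_id").to_csv(out / "truth.csv", index=False)

print(f"species models      : {len(sim.models)}")
print(f"analyser loads      : {len(sim.analyser)}  (rows in features.csv)")
print(f"spectroscopy loads  : {len(sim.spectroscopy)}  (after {config.n_dropped} drops)")
print(f"features per load   : {ps.N_SPECTRO_FEATURES} (spectroscopy) / "
      f"{len(ps.ANALYSER_FEATURE_NAMES)} (analyser)")
print(f"tones               : {sorted(set(m.tone for m in sim.models))}")
# The two tables describe the same loads measured two ways; the analyser table
# keeps all 336 loads while a few spectroscopy measurements are lost, as in a
# real field campaign.
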