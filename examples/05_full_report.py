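"""Full pipeline: synthetic data set on disk -> manifest -> run report.

Writes titrations at four temperatures (using the published per-temperature
binding constants as generating truth), a donor/acceptor band pair, an EEM
and a CD scan into a temporary directory, then runs every analysis stage and
prints the consolidated report.
"""

import tempfile
from pathlib import Path

from albuquench import RunConfig, run_pipeline
from albuquench.spectra_io import write_eem, write_spectrum, write_titration
from albuquench.synthetic_data import (
    make_cd,
    make_eem,
    make_fret_pair,
    make_titration,
    paper_preset,
)

spec = paper_preset(seed=1)

with tempfile.TemporaryDirectory() as tmp:
    base = Path(tmp)
    manifest = {"titrations": []}
    for t in spec.temperatures_K:
        name = f"titration_{t:g}K.tsv"
        write_titration(make_titration(spec, t), base / name)
        manifest["titrations"].append({
            "path": name, "temperature_K": t,
            "protein_conc_M": spec.protein_conc_M,
            "quencher_concs_M": list(spec.quencher_concs_M),
        })
    donor, acceptor = make_fret_pair(spec)
    write_spectrum(donor, base / "donor.tsv")
    write_spectrum(acceptor, base / "acceptor.tsv")
    manifest["fret"] = {"donor": "donor.tsv", "acceptor": "acceptor.tsv",
                        "f_ratio": 0.55}
    write_eem(make_eem(spec), base / "eem.tsv")
    manifest["eem"] = {"path": "eem.tsv", "min_separation_nm": 20,
                       "sync_deltas_nm": [15, 60]}
    write_spectrum(make_cd(spec), base / "cd.tsv")
    manifest["cd"] = {"path": "cd.tsv", "conc_mg_ml": spec.cd_conc_mg_ml,
                      "path_cm": spec.cd_path_cm,
                      "mean_residue_weight_Da": spec.mean_residue_weight_Da}

    config = RunConfig(intensity_readout="per_spectrum_max")
    report = run_pipeline(config, manifest, base_dir=base)
    print(report.to_text())
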