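"""Point statistics of aggregation: NND, SSI, multi-neighbour distances and
edge-corrected surrounding-fly profiles, clustered versus dispersed.
"""
import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from flysocial.core import ArenaSpec, Configuration
from flysocial.spatial import (
    distance_matrix,
    neighbor_summary,
    social_space_index,
    surround_profiles,
)
from flysocial.synthetic import SceneParams, gen_clustered_config, gen_dispersed_config

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0) -> None:
    RESULTS.mkdir(exist_ok=True)
    arena = ArenaSpec()
    pools = {
        "clustered": [
            gen_clustered_config(SceneParams(n_flies=50, seed=seed + s))[0]
            for s in range(10)
        ],
        "dispersed": [
            gen_dispersed_config(50, arena, hardcore=2.5, seed=seed + 100 + s)
            for s in range(10)
        ],
    }
    summary_rows, profile_rows = [], []
    for name, configs in pools.items():
        ssis, nnds, multi8 = [], [], []
        for cfg in configs:
            ns = neighbor_summary(distance_matrix(cfg))
            ssis.append(social_space_index(ns).ssi)
            nnds.append(ns.mean_nnd)
            multi8.append(ns.multi_neighbor_mean[8])
        summary_rows.append(
            {
                "config": name,
                "mean_nnd_mm": np.mean(nnds),
                "ssi": np.mean(ssis),
                "mean_8_neighbour_mm": np.mean(multi8),
            }
        )
        prof = surround_profiles(configs, bin_width=1.0)
        for k in range(len(prof.raw_count)):
            profile_rows.append(
                {
                    "config": name,
                    "bin_lo_mm": prof.bin_edges[k],
                    "bin_hi_mm": prof.bin_edges[k + 1],
                    "raw": prof.raw_count[k],
                    "adjusted": prof.adjusted_count[k],
                    "density_per_mm2": prof.density[k],
                }
            )
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(RESULTS / "spatial_summary.csv", index=False)
    pd.DataFrame(profile_rows).to_csv(RESULTS / "surround_profiles.csv", index=False)
    print(summary.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
    print(
        "\nclustered groups keep near neighbours inside 5 mm (SSI near 100) "
        "while the hard-core null spreads them out; profiles written to "
        f"{RESULTS}/surround_profiles.csv"
    )


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
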