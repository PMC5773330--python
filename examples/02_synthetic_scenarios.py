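"""Community assembly scenarios with known truth.

Generates the three reference scenarios (environmental filtering on a
conserved trait, limiting similarity, neutral placement) and shows how the
median per-cell SES.MPD at the 20-m scale recovers each mechanism:
clustering (negative), overdispersion (positive), and calibration near zero.
"""

import warnings

warnings.filterwarnings("ignore")

from phylodisp import build_communities, ses_table
from phylodisp.synthetic import generate_scenario, scenario_preset

for name in ("filtering", "limiting_similarity", "neutral"):
    sc = generate_scenario(scenario_preset(name, seed=11))
    comm = build_communities(sc.stems, cell_size=20.0, size_class="all",
                             plot_size=300.0)
    tab = ses_table(comm, sc.tree.cophenetic(), metric="mpd", n_null=499,
                    seed=5)
    z = tab.ses.dropna()
    print(f"{name:22s} stems={len(sc.stems):6d}  cells={len(z):4d}  "
          f"median SES.MPD={z.median():+.2f}  share<0={100 * (z < 0).mean():.0f}%")

print("\nFiltering on a conserved trait draws co-occurring species from the"
      "\nsame clades (clustering); limiting similarity spaces species out in"
      "\ntrait, hence phylogeny (overdispersion); neutral placement stays"
      "\nnear SES = 0.")
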