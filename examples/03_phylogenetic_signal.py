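"""Blomberg's K at the species-pool and community level.

Evolves one Brownian (conserved) and one shuffled (signal-free) trait on a
41-tip tree, tests pool-level signal, then re-tests the conserved trait on
the species subsets actually co-occurring in 20-m cells of a filtering
scenario and compares phylogenetically clustered against overdispersed cells.
"""

import warnings

warnings.filterwarnings("ignore")

from phylodisp import (build_communities, classify_pattern, community_signal,
                       compare_signal_by_pattern, k_test, ses_table)
from phylodisp.synthetic import generate_scenario, scenario_preset

sc = generate_scenario(scenario_preset("filtering", seed=17))

print("pool-level signal (999 trait shuffles):")
for trait in ("conserved", "labile"):
    r = k_test(sc.tree, sc.traits[trait], n_perm=999, seed=3, trait=trait)
    print(f"  {trait:10s} K = {r.K:5.3f}   p = {r.p:.3f}   n = {r.n_taxa}")

comm = build_communities(sc.stems, 20.0, "all", 300.0)
sig = community_signal(sc.tree, sc.traits["conserved"], comm, min_taxa=4,
                       n_perm=199, seed=7, trait="conserved")
ok = sig["K"].notna()
print(f"\ncommunity-level K (conserved trait): {ok.sum()} cells, "
      f"mean K = {sig.loc[ok, 'K'].mean():.3f}")

phylo = ses_table(comm, sc.tree.cophenetic(), "mpd", n_null=499, seed=9)
patterns = phylo["ses"].map(classify_pattern)
cmp = compare_signal_by_pattern(sig, patterns)
print(f"clustered cells      (n={cmp.n_clustered:3d}): mean K = "
      f"{cmp.mean_clustered:.3f}")
print(f"overdispersed cells  (n={cmp.n_overdispersed:3d}): mean K = "
      f"{cmp.mean_overdispersed:.3f}")
print(f"Welch t = {cmp.t:.2f}, p = {cmp.p:.3g}")
print("\nCommunity-level signal sits below the pool level, and clustered"
      "\ncells carry less signal than overdispersed ones — local assembly"
      "\nfilters out part of the pool's phylogenetic structure.")
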