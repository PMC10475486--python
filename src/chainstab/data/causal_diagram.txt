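# Causal diagram over community features and downstream stability.
# Syntax: "parent -> child" edges; "latent: node" marks nodes that cannot
# be used in adjustment sets.

# richness drives the interaction totals and degrees in its patch
richness_up -> total_pos_up
richness_up -> total_neg_up
richness_up -> mean_degree_up
richness_down -> total_pos_down
richness_down -> total_neg_down
richness_down -> mean_degree_down

# both richnesses drive the cross-patch (trans) totals and degree
richness_up -> total_pos_trans
richness_up -> total_neg_trans
richness_up -> mean_degree_trans
richness_down -> total_pos_trans
richness_down -> total_neg_trans
richness_down -> mean_degree_trans

# within-patch totals drive resistance to invasion in that patch
total_pos_up -> resistance_invasion_up
total_neg_up -> resistance_invasion_up
total_pos_down -> resistance_invasion_down
total_neg_down -> resistance_invasion_down

# upstream invasion resistance shields the downstream environment
resistance_invasion_up -> structural_persistence

# trans totals act on both stability metrics
total_pos_trans -> structural_persistence
total_pos_trans -> resistance_invasion_down
total_neg_trans -> structural_persistence
total_neg_trans -> resistance_invasion_down

# migration parameters weight both stability metrics
rho -> structural_persistence
rho -> resistance_invasion_down
mu -> structural_persistence
mu -> resistance_invasion_down

# stability is composed of the two metrics
structural_persistence -> stability
resistance_invasion_down -> stability

latent: resistance_invasion_up
latent: structural_persistence
latent: resistance_invasion_down
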