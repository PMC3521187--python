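# Canonical feature schema: one row per feature column emitted by the extractor.
# Metadata columns (chain, resnum, icode, residue, side, seq_index, n_interface)
# are not features.  The nominal inventory in the hot-spot literature is 6
# sequence + 62 structure features but never enumerates them exactly; this
# reconstruction carries 36 per-state PSAIA-style aggregates, 13 relative
# changes, 18 burial/neighbourhood descriptors and 6 sequence properties
# (73 columns), and flags the count mismatch here rather than hiding it.
name	group
asa_total_bound	per_state
asa_backbone_bound	per_state
asa_side_chain_bound	per_state
asa_polar_bound	per_state
asa_non_polar_bound	per_state
rasa_total_bound	per_state
rasa_backbone_bound	per_state
rasa_side_chain_bound	per_state
rasa_polar_bound	per_state
rasa_non_polar_bound	per_state
di_total_mean_bound	per_state
di_side_chain_mean_bound	per_state
di_max_bound	per_state
di_min_bound	per_state
pi_total_mean_bound	per_state
pi_side_chain_mean_bound	per_state
pi_max_bound	per_state
pi_min_bound	per_state
asa_total_unbound	per_state
asa_backbone_unbound	per_state
asa_side_chain_unbound	per_state
asa_polar_unbound	per_state
asa_non_polar_unbound	per_state
rasa_total_unbound	per_state
rasa_backbone_unbound	per_state
rasa_side_chain_unbound	per_state
rasa_polar_unbound	per_state
rasa_non_polar_unbound	per_state
di_total_mean_unbound	per_state
di_side_chain_mean_unbound	per_state
di_max_unbound	per_state
di_min_unbound	per_state
pi_total_mean_unbound	per_state
pi_side_chain_mean_unbound	per_state
pi_max_unbound	per_state
pi_min_unbound	per_state
rc_asa_total	relative_change
rc_asa_backbone	relative_change
rc_asa_side_chain	relative_change
rc_asa_polar	relative_change
rc_asa_non_polar	relative_change
rc_di_total_mean	relative_change
rc_di_side_chain_mean	relative_change
rc_di_max	relative_change
rc_di_min	relative_change
rc_pi_total_mean	relative_change
rc_pi_side_chain_mean	relative_change
rc_pi_max	relative_change
rc_pi_min	relative_change
delta_tot	burial_neighbourhood
core_rim	burial_neighbourhood
sa_ratio5	burial_neighbourhood
pos_per	burial_neighbourhood
max_asa	burial_neighbourhood
rot4	burial_neighbourhood
rot5	burial_neighbourhood
hp5	burial_neighbourhood
atmn4	burial_neighbourhood
atmn5	burial_neighbourhood
wt_rot4	burial_neighbourhood
wt_rot5	burial_neighbourhood
plast4	burial_neighbourhood
plast5	burial_neighbourhood
fp9n	burial_neighbourhood
fp9e	burial_neighbourhood
fp10n	burial_neighbourhood
fp10e	burial_neighbourhood
atom_count	sequence
eiip	sequence
hydrophobicity	sequence
hydrophilicity	sequence
propensity	sequence
isoelectric_point	sequence
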