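comparison_id,analysis,group_a,group_b,expected_label
elec_indep_of_chem,electrical_by_chemical_status,chem_connected,chem_unconnected,NS
chem_indep_of_elec,chemical_by_electrical_status,coupled,uncoupled,NS
elec_sparse_vs_unlabelled,electrical_quadruple_unlabelled_control,sparse_cluster,non_lineage,p<0.05
chem_sparse_vs_unlabelled,chemical_quadruple_unlabelled_control,sparse_cluster,non_lineage,NS
elec_sparse_vs_dense_control,electrical_quadruple_dense_control,sparse_cluster,non_lineage,p<0.001
chem_sparse_vs_dense_control,chemical_quadruple_dense_control,sparse_cluster,non_lineage,NS
coupling_nonFS_lineage_effect,coupling_by_subtype,sparse_nonFS_nonFS,non_lineage_nonFS_nonFS,p<0.001
coupling_FS_lineage_effect,coupling_by_subtype,sparse_FS_FS,non_lineage_FS_FS,p<0.01
coupling_age_P7_P10,coupling_by_age,sparse_P7_P10,non_lineage_P7_P10,NS
coordinated_sparse_by_coupling,coordinated_output,sparse_coupled,sparse_uncoupled,p<0.01
coordinated_non_lineage_by_coupling,coordinated_output,non_lineage_coupled,non_lineage_uncoupled,NS
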