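analysis,group,k,n,printed_pct,description
dual_overall,electrical,44,134,,sparsely labelled cluster pairs electrically coupled (dual recordings)
dual_overall,chemical,34,134,,sparsely labelled cluster pairs chemically connected (dual recordings)
dual_overall,both,11,134,,sparsely labelled cluster pairs with both synapse types
electrical_by_chemical_status,chem_connected,11,34,32.4,electrical coupling among chemically connected pairs
electrical_by_chemical_status,chem_unconnected,33,100,33.0,electrical coupling among non-chemically-connected pairs
chemical_by_electrical_status,coupled,11,44,25.0,chemical connection among electrically coupled pairs
chemical_by_electrical_status,uncoupled,23,90,25.6,chemical connection among non-coupled pairs
electrical_quadruple_unlabelled_control,sparse_cluster,9,31,29.0,coupling between sparsely labelled cluster pairs (quadruples with unlabelled controls)
electrical_quadruple_unlabelled_control,non_lineage,6,60,10.0,coupling between labelled/unlabelled non-lineage pairs
chemical_quadruple_unlabelled_control,sparse_cluster,9,31,29.0,chemical connection between sparsely labelled cluster pairs
chemical_quadruple_unlabelled_control,non_lineage,16,60,26.7,chemical connection between non-lineage pairs
electrical_quadruple_dense_control,sparse_cluster,27,80,33.8,coupling between sparse dual-labelled cluster pairs (dense-label controls)
electrical_quadruple_dense_control,non_lineage,59,462,12.8,coupling between sparse-vs-dense non-lineage pairs
electrical_quadruple_dense_control,dense_dense,15,115,13.0,coupling between densely labelled pairs
chemical_quadruple_dense_control,sparse_cluster,19,80,23.8,chemical connection between sparse dual-labelled cluster pairs
chemical_quadruple_dense_control,non_lineage,147,462,31.8,chemical connection between sparse-vs-dense non-lineage pairs
chemical_quadruple_dense_control,dense_dense,26,115,22.6,chemical connection between densely labelled pairs
coupling_by_subtype,sparse_nonFS_nonFS,49,79,62.0,coupling between sparse non-fast-spiking same-subtype pairs
coupling_by_subtype,sparse_FS_FS,20,52,38.5,coupling between sparse fast-spiking same-subtype pairs
coupling_by_subtype,non_lineage_nonFS_nonFS,33,166,19.9,coupling between non-lineage non-fast-spiking pairs
coupling_by_subtype,non_lineage_FS_FS,21,117,17.9,coupling between non-lineage fast-spiking pairs
coupling_by_distance,non_lineage_lt20um,4,7,57.1,coupling between neighbouring (<20 um) non-lineage same-subtype pairs
coupling_by_distance,non_lineage_gt150um,3,67,4.5,coupling between distant (>150 um) non-lineage same-subtype pairs
coupling_by_age,sparse_P7_P10,4,21,19.0,coupling between sparse cluster pairs at ages P7-P10
coupling_by_age,non_lineage_P7_P10,16,131,12.2,coupling between non-lineage pairs at ages P7-P10
coordinated_output,sparse_coupled,14,35,40.0,coupled sparse pairs giving inhibitory output to a common pyramidal neuron
coordinated_output,sparse_uncoupled,14,95,14.7,non-coupled sparse pairs giving output to a common pyramidal neuron
coordinated_output,non_lineage_coupled,1,15,6.7,coupled non-lineage pairs giving output to a common pyramidal neuron
coordinated_output,non_lineage_uncoupled,10,107,9.3,non-coupled non-lineage pairs giving output to a common pyramidal neuron
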