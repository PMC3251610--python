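genotype_id	accession_id	platform	read_length_min_bp	read_length_max_bp	read_length_avg_bp	n_reads	total_bases_mb
RHA280	PI 552943	sanger	100	809	397	20892	8.3
RHA801	PI 599768	sanger	100	814	425	22603	9.6
HA89	PI 599773	sanger	100	923	712	39569	28
HA300b		sanger	85	546	354	1485	0.5
PSC8		sanger	100	922	478	15837	7.6
EMIL		sanger	101	625	356	2169	0.8
ANN1238		sanger	100	1013	713	27957	30
HA89	PI 599773	flx454	50	622	285	66851	19
RHA373	PI 560141	illumina_se	36	36	36	21601273	777.7
RHA415	PI 607506	illumina_se	36	36	36	11341180	408.3
HA383	PI 578872	illumina_se	36	36	36	12717269	457.8
HA434	PI 633744	illumina_se	36	36	36	25661886	923.8
RHA455	PI 642774	illumina_pe	180	180	180	4673377	841.2
RHA468		illumina_pe	180	180	180	4459305	802.7
HA89	PI 599773	illumina_pe	180	180	180	4943677	889.9
HA412-HO	PI 642777	illumina_pe	180	180	180	3690226	664.2
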