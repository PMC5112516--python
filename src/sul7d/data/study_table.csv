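# Transcription of the study's printed per-protein table (decimal commas
# normalised to points). mw_measured_da: mass spectrometry; mw_tagged_calc_da:
# calculated from the tagged construct sequence. kd_um / n_bases from the
# fluorescence titration fits; tm_c from DSC. aggregates marks irreversible
# unfolding at high temperature; tm_group is the study's stability grouping.
name,accession,mw_measured_da,mw_tagged_calc_da,yield_mg_per_l,kd_um,kd_err_um,n_bases,n_err_bases,tm_c,aggregates,tm_group
Sac7d,P13123,9108,9103,8.0,13,1,6.4,0.2,89.6,False,low
Sac7e,P13125,8968,8964,5.5,11,1,6.9,0.4,85.5,False,low
Mse7,,8477,8473,6.5,15,1,6.2,0.3,87.4,True,low
Mcu7,,8449,8446,7.0,16,1,6.7,0.2,88.8,True,low
Aho7a,,8533,8531,5.0,16,1,6.1,0.1,94.7,False,high
Aho7b,,8618,8615,6.0,13,1,5.7,0.3,95.8,False,high
Aho7c,,8374,8372,8.0,16,1,5.7,0.2,96.8,False,high
Sto7,,8808,8804,8.5,14,1,6.5,0.3,100.0,False,high
Ssh7b,,8795,8790,10.0,22,1,6.3,0.2,89.0,False,low
Sis7a,,8806,8803,8.0,15,2,6.7,0.4,95.6,False,high
Sis7b,,8797,8791,7.0,16,1,6.0,0.3,87.2,False,low
Ssh7a,,8776,8773,7.0,18,2,7.9,0.4,95.6,False,high
Sso7d,P39476,8778,8774,8.0,17,1,8.1,0.3,96.5,False,high
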