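species,strategy,pollen_mean,pollen_se,pollen_n,ovule_mean,ovule_se,ovule_mean_low,ovule_n,po_mean,po_se,po_var
Anacamptis morio,deceptive,104817,3207,6,7347,952,9827,9,18,2.9,49
Anacamptis pyramidalis,deceptive,74013,2407,8,3435,232,4350,11,24,1.7,22
Dactylorhiza fuchsii,rewarding,51917,4075,6,2659,327,3413,8,25,5.0,152
Dactylorhiza incarnata,deceptive,79113,2761,8,6715,846,9030,11,13,1.7,23
Dactylorhiza majalis,deceptive,72050,2422,10,4528,455,5447,12,19,2.2,46
Dactylorhiza viridis,rewarding,35588,2823,8,1413,134,1772,12,29,4.3,147
Orchis militaris,deceptive,176417,26062,6,12616,1296,14183,7,15,2.2,30
Platanthera bifolia,rewarding,215978,25687,6,3779,514,4930,6,59,5.4,175
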