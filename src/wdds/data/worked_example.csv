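Sample ID,Animal ID,Latitude,Longitude,Spatial uncertainty,Collection day,Collection month,Collection year,Sample collection method,Sample collection body part,Sample material,Host identification,Organism sex,Live capture,Host life stage,Age,Age units,Mass,Mass units,Length,Length measurement,Length units,Organism quantity,Organism quantity units,Detection target,Detection method,Forward primer sequence,Reverse primer sequence,Gene target,Primer citation,Probe target,Probe type,Probe citation,Detection outcome,Detection measurement,Detection measurement units,Parasite identification,Parasite ID,Parasite life stage,GenBank accession
OS BZ19-95,BZ19-114,17.7643,−88.6521,,23,04,2019,Swab,Mouth,,Desmodus rotundus,male,TRUE,subadult,,,0.023,kg,,,,,,Coronaviridae,semi-nested PCR,,,RdRp,10.3390/v9120364,,,,positive,,,Alphacoronavirus,,,OM240578
RS BZ19-95,BZ19-114,17.7643,−88.6521,,23,04,2019,Swab,Rectum,,Desmodus rotundus,male,TRUE,subadult,,,0.023,kg,,,,,,Coronaviridae,semi-nested PCR,,,RdRp,10.3390/v9120364,,,,negative,,,,,,
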