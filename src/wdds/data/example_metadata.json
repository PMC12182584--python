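{
  "Title": "Coronavirus screening of vampire bats in Belize (illustrative example)",
  "Description": "Synthetic example project metadata distributed with the package to illustrate the 24-property metadata document. Names and identifiers are placeholders (the dataset DOI uses the DataCite test prefix); no coordinates in the companion dataset are obfuscated.",
  "Creators": [
    {"name": "Example Researcher", "orcid": "0000-0002-1825-0097", "affiliation": "Example University", "ror": "05gq02987"}
  ],
  "Creator ORCID": "0000-0002-1825-0097",
  "Creator affiliation": "Example University",
  "Affiliation ROR": "05gq02987",
  "Publication year": 2025,
  "Publisher": "Zenodo",
  "Resource type": "Dataset",
  "Identifier": "10.5072/example-wildlife-disease-dataset",
  "License": "CC-BY-4.0",
  "Subjects": ["wildlife disease", "coronavirus", "Desmodus rotundus"],
  "Language": "en",
  "Version": "1.0.0",
  "Funder name": "Example Science Foundation",
  "Funder identifier": "10.13039/100000001",
  "Award number": "EX-0000",
  "Related identifier": "10.3390/v9120364",
  "Related identifier type": "DOI",
  "Relation type": "IsSupplementTo",
  "Contributors": ["Example Curator"],
  "Contributor type": "DataCurator",
  "Coverage dates": "2019-04",
  "Geographic coverage description": "Orange Walk District, Belize"
}
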