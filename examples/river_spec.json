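{
  "length": 300,
  "divergence": 8,
  "n": 40,
  "seed": 11,
  "divergence_synonymous": true,
  "species": [
    {
      "species": "Salmo trutta",
      "tonnage": 348.6,
      "n_haplotypes": 3,
      "n_samples": 38,
      "trophic_level": 3.5,
      "taxonomy": {
        "species": "Salmo trutta",
        "genus": "Salmo",
        "family": "Salmonidae",
        "order": "Salmoniformes",
        "class_": "Actinopterygii",
        "phylum": "Chordata"
      }
    },
    {
      "species": "Salmo salar",
      "tonnage": 9.2,
      "n_haplotypes": 1,
      "n_samples": 2,
      "trophic_level": 4.4,
      "taxonomy": {
        "species": "Salmo salar",
        "genus": "Salmo",
        "family": "Salmonidae",
        "order": "Salmoniformes",
        "class_": "Actinopterygii",
        "phylum": "Chordata"
      }
    }
  ]
}
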