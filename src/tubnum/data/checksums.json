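{
 "accessions.tsv": "0bf71c7f082d6aabd418a48f457cb24e14b0a8d7d33d5e5261fb190399bd13ae",
 "doublecortin_footprint.tsv": "fcdf8f573d3c2469a26c39aabee5c49641583c8f51ee49ddedfc73675e9d9b02",
 "dynein_footprint.tsv": "de0dd4633532696b5afef4818d0e04715c2d6f423eafbb788c46b741b17a13a7",
 "ptm_sites_alpha.tsv": "74783d2a36506d9228d408ba01a288fd4a59fbf2977c8f29d8b0ca522ca4bca6",
 "ptm_sites_beta.tsv": "1377a2c810de2aded2d11f1c56065ee2e713a0a1895d3904ec2953c085f4fa9b",
 "table1.tsv": "8756c30768b6c7e18634639d889630dbbb472571ae1cde594bfd89b8c408338d",
 "table2.tsv": "8c8e8c23e6fac5996c65ab644dbbecd1efafdb52096da7181c3a79a55655207a",
 "table3.tsv": "0e8d066cb441943c1fcdc266d532692dcce100abc032d3096fc1d0b347242c2b",
 "table4.tsv": "3f7b849f88f922dc7af4a9d4c274aa1f4cfcb37cc079bf8650dc038e222e2820"
}
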