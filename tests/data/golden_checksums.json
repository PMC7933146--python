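{
 "00_inputs/annotations.tsv": "5d080d770fe3022e50b17418bef9959fa49d7142e87eb1065f6f51a71285d5ff",
 "00_inputs/expression.tsv": "50694c463c55a28805a9f7c6c201e1e360787fac2ecc1d0e0b9ed6c0d873af08",
 "00_inputs/expression_dev.tsv": "c76446d1da38a66438623a4120214ad2ed243e0a07f64dc621688f28aef2e7e0",
 "00_inputs/kd_e1.tsv": "0c3f14b5d680108dde16626fd95568fe4245a73050202ed2a85b523393adb02f",
 "00_inputs/kd_e2.tsv": "3da75a8be1963fd98562035d4b7830057476f684a7f5c50256d859fec87c4e34",
 "00_inputs/kd_tal.tsv": "992ba04a62a6162b51a3fe44402f4c2d2c6d4070eb8e1e4ffc365d6d4e61257a",
 "00_inputs/query_peaks.bed": "f60de2bfe2b90d32d9a3223344d96dac3ef9a053a1b59ac1c85902e819019f60",
 "00_inputs/reference_peaks.bed": "58a48166d16e4b06c3f0f3d3ac3c7307bc3926ebf517a8d37c33787622e1bf0c",
 "00_inputs/spectral_counts.tsv": "9886bc51046859ba61217bd9884f8822b81f602ce949bc4c030be1497ab9082f",
 "00_inputs/truth.json": "d77b0d0c81849be466684876359a579bda7aa6ba422b3bf9d6e710c16687f70d",
 "01_preprocess/expression_filtered.tsv": "50694c463c55a28805a9f7c6c201e1e360787fac2ecc1d0e0b9ed6c0d873af08",
 "01_preprocess/expression_network_filtered.tsv": "c76446d1da38a66438623a4120214ad2ed243e0a07f64dc621688f28aef2e7e0",
 "02_network/provenance.json": "3efb1dfeeb093ecd3316608bcdb0184f13102c22089a8f541c9ec1ad9a3bcf28",
 "02_network/regulons.gmt": "fc4d83ef7ca422c00ef48f6e66d8d7cf2df3983af0a7d6832b7ede0effe4d323",
 "02_network/regulons.tsv": "798f37e936bf0c905b11f60f680c05b942036378f650043abf20b29c7e16f98b",
 "03_activity/activity.tsv": "5f6f1d4b6c1bd16d71f318b819a9ef73158eca5fff3c798c98ad6f0ca2e698b1",
 "04_diff_activity/differential_activity.tsv": "d8cea49c153ed40e5c10fee356e0342e27182b654a4f26935191682f172dbc0d",
 "05_gsea/gene_sets.gmt": "f57a4b9f549e64461ca184f0e14ab40f4aa4c28e106d971d95a4946f0397c2c0",
 "05_gsea/gsea_results.tsv": "2d3368e9ad4db8434fa191d5305c691428fac4354dc1123d997015c718cdf823",
 "05_gsea/ranked.rnk": "8128cefd3ec749f3dc2696016f8e568af51bdc63e1421526abf03228d5dadf05",
 "06_apms/interactor_calls.tsv": "57f981d4a2fef154889d4c883167803db52c3f19bb4a73868e9df1c56ef76822",
 "06_peaks/overlap.tsv": "fb97ba6de9e7b79a1dc3de1e66260b819e16e196f127667184ed7aeb35ad9406"
}
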