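{
 "catalog.tsv": "eff192742b7341c907ceb471d718b255023b3aa8d7a08376c0072f49c8ce754a",
 "config.json": "b5e8e13d7fc0a76c28a81d501cbb4fe7b959d7154dff0c6cb158369f423dc2bc",
 "de_root_vs_flower.tsv": "7d8a15a7f91e1ab9794222414eff3a1894cb4294a0495e9a76b7777f944ce6a5",
 "de_root_vs_leaf.tsv": "11f1ce238ddf3051f3dba75ea79668174db696d12bc89e1f24b4286a5070dcca",
 "de_root_vs_stem.tsv": "dcd30ab8400d8e161fdedab059c1d22906f6b0fd890de2c628a302ae98524bad",
 "drclr.fa": "a355673de16013bb6c157c0a4cc8c11aff775deb22a4d6331811324954de06a7",
 "drclr_vs_contigs.psl": "17ee1f96e3f63e2361bf7b63c1f132c61b13423efafb3bd8f83146c3de2e385c",
 "events.bed": "22207819121b3ccce06704930a774ec9aa4f708e99a9b2517d0201ea2713ee1e",
 "expression.tsv": "b1ed15af812089891055ab0759db56279be1f94914337b957cc4b051f336daac",
 "groups.tsv": "0ab93aa90d8f362cdf08d250e5cf180463ed05066deed516b3cbd1524bd548ea",
 "isoform_histogram.tsv": "ffae4d5c30890d0bb4e79e15f43c703e75dd53bffa61b12b0a6955335566f6a3",
 "junction_support.tsv": "a0856c2096e77f438c2389a8b4f2824f04aae56343d8dd86e76d6bcd95feff75",
 "lrd.fa": "9b43060c31f5becd31ba9de5363006bed42144343b89283b7e9e85518d44a34c",
 "map_report.tsv": "531ab6dc323119014010969a31d18ed3fd0032da355c303ac06f7395e2321351",
 "removed.tsv": "5f11f6239f0e759f8e81ce84820ed70f81ef7b7b2da68e0b0162e945676b43fd",
 "root_down.txt": "ef2e46d9aa111ac071a0857203387df5d3bca20d55fc71fb9da3d48734f65e8e",
 "root_up.txt": "dc9d609cd98681c3318a74aaf7996c5973b31079f6a0d919b271e9c0d2c6427a",
 "sim/contigs.fa": "c3de67669a9cfd68b2f42cb8b9bf8ba1e09d100245c2a3e30d490bb3870c7f25",
 "sim/flower_1.fq": "da9222832bf52bb35c3c0795a194a48d1e2606e81dad07435b2936e86b4dae39",
 "sim/flower_2.fq": "a781a3ddd5153f614d8374d6eb3db3073e5b2a9826b7236491507afff2a10aaa",
 "sim/flower_3.fq": "c8d8694dc0e38aefa0c85855897ffdad0bfffd1f4da27d9e6257bd8304f7827f",
 "sim/fragments.fa": "add490df938dac97e67954285c7f994f7295e831beaf91fac074109bd7990d72",
 "sim/leaf_1.fq": "1c2081edad74eeb747b04dc825e2888af32f9d4a581f90f50890163bb6d93687",
 "sim/leaf_2.fq": "e6ffa159de707f805f94f8a6602d7a1f2962696b9fd2d38896cd92c63437bc5d",
 "sim/leaf_3.fq": "6153042216c01f85b66afec7f74be9caab9aec8496e30833a20fc8fc65de7f92",
 "sim/long_reads.fa": "5c76d595a4e6f10521c204d72e01ecd2590aa2df86e857399b244ffb8648f853",
 "sim/manifest.json": "1ac1c064616a57985741e3f5df2a9eef921dec9ddab90fd2340e436e2babf5b8",
 "sim/root_1.fq": "e4cb0c1ac58a892d662637a6f5e8c799201addd026caf277aa6afa89bb4c1c1d",
 "sim/root_2.fq": "2cf01a57a61109463ef87d733e640d6f9e62b4024d2f427fbb0553a46279ccff",
 "sim/root_3.fq": "a9ce990b892085ae06e93f6d59bfa41575eef8036d96f8d8487cbf36422f60a6",
 "sim/stem_1.fq": "df376b3077ee556213397b864a1533f8cf664143b9fdd8b07609fda5a1dca6ff",
 "sim/stem_2.fq": "9cafd90997b68ffe79b7b24b4226f28ab01241fbfc4d9b4fccbc244452dd726b",
 "sim/stem_3.fq": "2f6faadc71e92df0c05066d7077c2174b77ea1ef2d6320aff019a18f9a207126",
 "unresolved.txt": "e3b0c44298fc1c149afbf4c8996fb92427ae41e4649b934ca495991b7852b855"
}
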