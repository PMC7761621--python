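>VDAC1_SYN synthetic VDAC1-like scaffold (283 aa, initiator Met removed in mature chain)
MADGAEVTTRSEGDEFGYTKIAAGTTFYLAFKTKSENGLEFTSSGSANTETTKTEDEFIT
PYRVHWAHHSEILRVSTHLGGIGLWRLYVHAEPFGKLTFDSSFSPNTGKKKIGFVWDYWR
EHINLGCDVDFDIAGPSIRGALVLGYEGWLAGYQMNFETSKLKVTQSNFAVGYKYTEGAD
THVGWRTWGIVPDWLRSLLRKLETAVNLAWTAGNSNTRAGSPAKYQVDPDACFSAKVNNS
SLIGLGYTQTLKPGIKTDVEDRDGYDSFETSPIRVDEFTDLWH
>VDAC2_SYN synthetic VDAC2-like paralog
MADGTEVSTRSEGDEFGYTKIAAGTTFYLAFKTKSENGLEFTSSGSANTETTKTEDEFII
PYRVHWAHASEILRVSTHLGGIGLWRLYVHAEPFGKLTFDSSFSPNTGKKKIGFVWDYWR
EHINLGCDVDFDIAGPSIRGALVLGYEGWLAGYQMNFETSKLKVTQSNFAVGYKYTEGAV
THVTWRTWGEVPDWLRSLLRKLETAVNLAWTAGNSNTRAGSPAKYQVDPDACFSAKVNNS
SLIGLGYTQTLKPGIKTDVSDRDGYGSFETSPIRVDEFTALWH
>VDAC3_SYN synthetic VDAC3-like paralog
MADSAEVTLRSEGDEFGYTKIAAGTTFYLAFKTKSENGLEFTSSGSANTETTKTEDEVIT
PYRVHWAHHGEILRVSTHLGGIGLWRLYVHAEPFGKLTFDSSFSPNTGKKKIGFVWDYWR
EHINLGCDVDFDIAGPSIRGALVLGYEGWLAGYQMNFETSKLKVTQSNFAVGYKYTEGAD
IHVGSRTWGIDPDWLRSLLRKLETAVNLAWTAGNSNTRAGSPAKYQVDPDACFSAKVNNS
SLIGLGYTQTLKPGIKTDTEDRDGYDAFETSPIRVDEFTDVWH
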