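# synthetic stand-in pseudo-sequences for 20 common HLA class-I alleles
# allele names are real; 34-mer pseudo-sequences are randomly generated
allele	pseudo_sequence
HLA-A*01:01	VGGLVDFMFKHCACQYWQWKNPKGRHNCFCPTVT
HLA-A*02:01	WASHPCFLGPWNWDKREPKLMGRWDCGDIIFGHP
HLA-A*03:01	TQDRQSFEARIFQMMFDTHDVKLPLQVCHYVGGK
HLA-A*11:01	SHAAEFYHWNACSWGENMKIEIMWPVYPMGREIL
HLA-A*24:02	KEMLMCKAFMPIIYRIVMYISSMICGVLYTDMIQ
HLA-A*26:01	HPHFCLPIVSPGITCIMHFWVVEMGTWVLSENFR
HLA-A*31:01	ACVHQMCDNFMEPFPITGHWAASNIPIQLHIYWP
HLA-A*33:01	HRRCRIWFPVWICFYTTEDIDWGAEEILILPYDV
HLA-A*68:01	MPRAEECNLKKYILHYGETVDPVVVRCPDECCTC
HLA-A*68:02	CDSFHFDFWKNPPVQWVEYYNPLHESLGYQMGAN
HLA-B*07:02	QCGWICLSMGYFGYWEMSSMTGGDKWMNPVHLQG
HLA-B*08:01	ARARQKELPLMWEDEPILHTKFNWCSLSAVFFIF
HLA-B*15:01	TCMPTYQEWFDLFYDPIRFMPSRPWSKGKVPRQG
HLA-B*18:01	YGSTPKELWVFKTNPRIIEGIRWQKLMQQQFNRT
HLA-B*27:05	NSMRWVKANTNESCDDEAQCHTAPTSMKFQSQKF
HLA-B*35:01	RAYDKIRGFSQVLDWWEWAWYKNKNIKWGAFKGW
HLA-B*40:01	DRQTHTWGCNEGFLAIIAWWFAPGDWYYPQDKQI
HLA-B*44:02	NIVMCQFELMLMGESEVMICTHATIFWKKRKYRW
HLA-B*51:01	FFNFLLRMMAYPKVDCTGIRWSMSLVGNFHVDVH
HLA-B*57:01	HNCDAHDMFFLCQDCPVEEISMPHFEMPKPYIIW
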