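>acet1 synthetic placeholder protein (carbon monoxide dehydrogenase)
DINVTRTTVGSILCFEMEKVLTDGGSWDEGGEMQTEEQASQAAMQGDGIHNNFHEKNEAQ
YNGSTMLKELALAEIECRLGSDIAPIYSGMVTRISRLSEGGVIQGVVDHLTQQGVNTALL
ERIESSGVLEQLCPRDTTAVWLIETESLAFVIYDRVVTAKLNKVILEMITRKVNTMLLRI
ASKQVMIQAPHKNEKDLCPGKKIAKKPMFV
>acet2 synthetic placeholder protein (acetyl-CoA synthetase)
RNDDCGKREPYPTILSTWTELRIFDKEEDSGTPDLLEKIERGNKRAMVTAAVKNIKSCRP
TGEFCKQVEPESEDTLIHRSWNNPDQTEESVKRRIRGLTDFMGGAFLTLNFMISPWNSCG
DAKDREVKAVVEPSNSSRTGSVDEACSLPEPRIIPAVTLDLQLSYLKSRPLSEWTISSPS
RPEEPSLRVNMIYVAWDTIV
>acet3 synthetic placeholder protein (corrinoid iron-sulfur protein small subunit)
VAIKARDPGHTREGLAFTGIEADHLCVIMVDCNIITPVAEVGEREDLFHAKDVAKNNGGK
GIGYFMLTMLALAGILTVFDKENIKAFRGKSPYPKIGSTLQNMAFMGIDDDWVGQPVCCI
DNGTFQYNRAEMASARSSEYDYAAVFNYDTMRDLLVPLIDSTSPVIRESA
>acet4 synthetic placeholder protein (corrinoid iron-sulfur protein large subunit)
INAHDDCRCQGLLEDLSLLNNESKTGLHKTRASSYPINRDRSADEATIVTTDHQLKSKVR
GLSDLAVKNVGKNRRPLEGLVDQDAEKIERKGDVFDQPSVWGKDAWARFMLFVETCLRPR
KYEQVDAVAYEQEALNRTSGHKSHLEEENKTSSRFTITKLLQDPKESPLHSEIIKLQEYK
MFVAEMGEALAAMPVDLSVMDFEDKDNHKEMGEGGEELHNLYRAKMIEETHVKDPSTNQP
>sulfat1 synthetic placeholder protein (dissimilatory sulfite reductase)
QLEIGVALNSNLTGASEYSLPGAWASLAYTFEIKGGEIEEALQGFLDTRRHPPDKDAEPF
AKEGGQDDALSGLVPQLAHQLMLEVLRNLQWYGNPEIDDEINQEKVDGLQYSVDQAGAVA
AETGHQAASGDTEDTGKRAYLQASVMPKVALLMSSGSKGMDVSRAGTGAKVGDRVVDDAS
YRRVILLRYTDVWIRGRFDHDHFQTDIDRPSGFLLNHGCV
>but1 synthetic placeholder protein (butyryl-CoA dehydrogenase)
VIDALFSWIVKSHSFKETSINLDLRFFLLQKNTSFQWTCPPGKDSARIDTASRCLLAVER
GQLDQYLADNFKHSVFDSKLGAVQAVHPGMDSGMNAFPRCFASFLQKTEKSKLLSYFSIE
SETIERKSSAYGSLAMYLNMSAASETQLSKCTQLSFAEVKYERGGPTSIEARCTVLLEMV
FRGKYEREEP
>muc1 synthetic placeholder protein (sulfatase)
NAGSIVDMVVSGGDQRTGPQNFPGAPEDRVVSEDTGVDEGGDRQEQYKTNALQGNERAAA
ARLLGHGVLVVLMNNIYLIALTGFDFRYGKWEDKVRQEGIIAGLIVDQDSRLSLIALQMW
REQGKLIREEAISYKLYGSIFLQSEGLIVMSSAHSQYEIGKLQVHIFRAGTREPQLDLTP
TGGTNTPEFIGALMAIAKVGQTIGAVFWGKVLTPLHNLKVLRSDYFYSDL
>muc2 synthetic placeholder protein (alpha-N-acetylgalactosaminidase)
QTIEFGEPGCPEGGEKNPVATLVVRGEFQLIVGFLDSLTRGLWRRAKNIVNFIYENENLE
DATKRNDSAPESIPIVAIISGLTYVTKPAHFELASNLTKLIEENTMLSLIQTSSEKSVGP
KVNVRSRKRICHKAAQLTKRVAQYEEEVRGKIFSIEIQVYQTVQLRSSDLHKATRDPANR
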