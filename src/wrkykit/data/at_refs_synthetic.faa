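>AEE85928.1 synthetic_IId_prototype
NKDTGSSYKAGGYNAPNVPLAVTEKYNSIIRRGNAKPDQKKGYPGKIVNKRKVIDRPDPRAPFNRFIAKNTKFWRKYGQKFAYLNGNETVPEMFRYMCEFDAYCQKLPNVVYQNKETPVYATFQDYSHVHLKKYYIRRYNGRTQANQNNYKMSYFVNYSPMPYLKEFIPDIGVYDRTNPQQEARAMETIKASDQR
>AAP21276.1 synthetic_IIe_prototype
DSEDSLIFGVYTGRVTRYKEETITMALVALNKSNNELPPSANYRIREIAVFEALEFTGGNFEVFMYQFLKYNYKLDFIEKRFAMNFFVRQQRGAVPYAFPLVMQNYAQEPKPGQNQGLDNGYAGKSRSLTSFYKQVMTETPWRKYGQKKPFLGLQSVAFPQDVNRAYMCIAQMLCMLNATDSRSDARRVIETQVFTDKHAHNRGMITKTSIIMVNPDQIANIEGT
>AAM78067.1 synthetic_IIa_prototype
MITLDATIGGSIENTLFWRKYGQKTYNSQTVRGSIAIMLDFVTNCLARDECYMLEGYIAVTNLSNNGPVETETFHQHFGQPLAVANNTKFEFGMQFKRFRANSLQEIPQQTYGNRTGYYEAKRTRAVMAYAYGPFPKQLILDKTPTKQRAFDRGEMKQGLLDIPFIAITTLILTKVMLMQVSDESTAMF
>ANM67410.1 synthetic_I_prototype
FVDAKPWRKYGQKATGAQQLNTFQYSCIDAVCSRYIMLPRFKTNINSQYDMGMYKHAHFFYRDEEQKRSNYEIMSLSGDGPVYLNFPRWRKYGQKGGYPGMSACLKNGCTFNKDPDGPQQLIQNADRKKQFKHMHRDELMGAELISVLQPMMIIMPFRFQPRNPGYSNDQMALISATVIQMRITYNRPPVRQYFEDVRMFK
>AAB63078.1 synthetic_IId_prototype
SYKDSTFTADAMRGNYLAAINKIAYKWRKYGQKSDLQQMDGLVGCVTGVFCTTAKQIRMRFSYDSEIFLTALQMHKHYSIQLEIQYTEQPQPEVTDNESDIVDDRQGEKGGTLPQEKKMTLPEAPMLAVKISLLEIPQKLQVMPDFTMLFVQYDQMSMIEITPAGDSGAERINMNRYMSYRIRTNQAFGMQIYITFAI
>ABH04558.1 synthetic_IIe_prototype
IIDGSYGMRNGVVELFFLETVVLTNSYTKRNMKMYNPYFTTLIMYGWRKYGQKPVQEIAQPQGYSCFQYDTCPIAQRGYGEAYQVESIKKKLIRGHDHREYVVKEYLMDFSGLEMFTAPPNAPEITDYGRGYVRGTEFDKLGEARPKFTPGETQLVIPKFERGMPVRPPGMSFVDEDIQIPVFLQGKSMLAEADFKFEFNDLNLSIAYIRQI
>AEE84006.1 synthetic_IIc_prototype
YIRESIPTKARVNNDNYGKITVQPYPLIFITPDYSRYFMAAYKFEEDADFGSTMDLRYPEPSINELSLELLISLMFNQKMGVKMDYGTQRKDKIDYEDVVGNDQVIGPRMFQEKRVTLTIKMQPQTKIFEKGVKLYNTNNPVSVGTTFYTPMPWRKYGQKFQLMQYYRGICVDEMCKPVQDENFKTGPAFRQAAKRMYNHTHDVGGASQFEFFFKDMITNMNAPLPPEALPYYRFEGPSAMGIQDTGMEFPVGPRRAM
>AEE84546.1 synthetic_IIb_prototype
VLESLYTRDLYSQAVFVAETTIKSKLGKISYSLEQSEMIEVTRGNNNKYENIQPAIVPRDITNLGRIPLGAPGRYRTESSYMPKRQPRVYQIPGANQMPMVMAQPSENYYNIKYTERDILNEVPALYIKNGKLTGRMLATEGQLDRNGWRKYGQKLYPKPNPIKSCIKTSFCAMPFKDMNAQRIFADQGFGGQYRHRHIKLKPSRMFKKPGDEFRIGV
>AEE82969.1 synthetic_III_prototype
PYLNLPQASQRDESSAFKAQWRKYGQKEYMLDTVADCAAIAVVPCKTYSRSTDSKPIPGKGNQMIPDDHACEVQTSSIAVVVPSRPFGQNLTKTMTSSVQLIKSLDVKVPISNDGTFQEVVLFMKNSVLLSGGLPTTSQRMYEFSMPYSSLSGIPVRDQRQSAFRLENLAKQPPSTEDRPEF
>AEC10646.1 synthetic_IIc_prototype
MSNRKMVQYSMYMAESSPWRKYGQKDNAMIEAAFSAGLRCSGLMCFQYSPQMYANVGMRYFAPNEVYIHTHPREPTPKFKGIVGTRMKYRTTPILNPAYDMQLLMKDFVEYGDGRGIKFRTQAYMVERQNRTNMGLSFEVKERRMARPRPPIREIRATPNKDQKRGKSQFDMGVFEPENKIAGEAVDQKGYVILSYYSPSDFFAGGYLDDDRPGISSADFTPPAKDPPTEKMFQVLGFTVFSQKISIPPNNRQLGRK
>ABD57509.1 synthetic_I_prototype
VSEEDMWRKYGQKPKVSRSVMEKSNCDEPKCYVPLDIVQGELLMILPASVQLVEHDHSERVPLNKAQGIVNGYWRKYGQKDPGNFDPDEAGCADQYCSMQPMYENDNMQQYGFFSYVKGYHTHEYVLDFVVGGYAQPTLAVNKVKDSYTGALFNNRPFTKRKLPQFGNSMGGMGLIGKEDTIKVAKIDVMPQTIAQVNYVGISYTSYANDRASYEGTQNNTMFQ
>AAQ62425.1 synthetic_IIc_prototype
PTQKRIDEAQPPRAYTMYARDAYVNTWRKYGQKSKSDYNAKRMTARTEAYAGCTIMSCSGASSKPEAILKVLATVRKPDLGHDHSGPMLIPYSAERSVRKDMIATIDNENMAPYRKGKQAKEYKILGRATQVNGGNAEFAESKQSYTQSRKKSYSPATKTLQLMEGILTKGDGKVIFVKELIEATQSYAMMPNNSYEKYSPKGSRVLVIGISPGDFFRSNINTNMRQNRGRNSENKGKVQQSTNAPMIE
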