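strains,od,od_wavelength_nm,ccp_days,kanamycin,hygromycin,paromomycin,geneticin,vancomycin,cefotaxime,carbenicillin,ticarcillin,efficiency_pct,reference
LBA4404,1.5,550,8,-,-,-,-,400,250,-,-,4.3-13.4,Jong et al.
LBA4404,0.8,550,4,25,-,-,-,100-300,-,-,-,0-4.6,Lemieux et al.
LBA4404; A2002,0.1,660,2,25,-,-,-,-,-,-,500,0-0.8,Ledger et al.
LBA4404; A281; Ach5; C58,0.5,660,6,50,-,-,-,400,250,-,-,0-0.75,van Wordragen et al. 1991
EHA101,0.1,660,3,35,-,-,-,-,250,-,-,0.06,Aida et al. 1992
LBA4404; A281; Ach5,0.5,660,2,50,-,-,-,400,250,-,-,0-10,Van Wordragen et al. 1992
LBA4404,0.6,660,2,-,-,-,-,400,250,-,-,1.4-4.6,de Jong et al. 1993
LBA4404,0.1,660,4,-,-,-,-,-,-,500,-,0-0.4,Courtney-Gutterson et al. 1993
EHA101; Ach5; C58; Bo542,0.7,660,1,25,5,-,-,400,500,-,-,1.04-12.14,Renou et al.
LBA4404; C58,0.5,660,2,15-25,-,-,-,-,500,-,-,0-6.3,Lowe et al.
A281,0.5,660,3,50-100,-,-,-,200,125,-,-,0-2.5,van Wordragen et al. 1994
LBA4404,0.1,660,3-5,100,-,-,-,-,-,500,-,0-0.4,Courtney-Gutterson et al. 1995
B6S3,0.1,660,1,100,-,-,-,-,200,-,500,17-47,Pavingerova et al.
LBA4404; AGL0,0.4-0.8,550,2,10-25,-,-,-,400,250,-,-,0.3-4.3,de Jong et al. 1995
EHA105; Ach5; A281; Chry5,2.2,660,3-5,50,-,-,-,-,-,500,-,4-7,Urban et al.
B6S3,0.1,660,1,100,-,-,-,-,200,-,500,3.8-4.7,Benetka and Pavingerova
AGL0,0.5,540,2,10,-,-,-,500,250,-,-,0-39.45,de Jong et al. 1996
C58; A281,0.1,660,2,25,-,-,-,-,500,-,-,0-11.3,Dolgov et al. 1997
AGL0,0.7-1,540,2,10,-,-,-,400,250,-,-,5.6-15.6,Fukai et al.
LBA4404,0.5,540,2,50,-,-,-,-,100,-,-,6.9-8.3,Oka et al.
A281; GV3101; C58; CBE21,0.6-0.9,600,3,10-50,10-15,-,-,-,500,-,-,0-3,Dolgov et al. 2001
LBA4404,0.1,660,4,20,-,-,-,-,-,-,500,3.4,Boase et al. 1998
LBA4404; EHA105,0.1,660,4,25,-,-,-,-,-,-,500,0-14.2,Boase et al. 2002
LBA4404,0.5,600,4,25,-,-,-,-,500,-,-,3.4-8.5,Fu et al.
LBA4404,0.5,600,2,20,-,-,-,-,250,-,-,6.9,Kim et al. 2002
LBA4404,0.5,600,2,50,-,-,-,-,250,-,-,7.6,Kim et al. 2004
EHA105,2.2,600,5,-,-,50,-,-,-,500,-,0.5-4.1,John et al.
EHA101,0.2,600,3,15,15,-,15,-,250,-,-,3.4,Shinoyama et al. 2002
LBA4404,0.5,660,3,15,15,-,15,-,250,-,-,0-2.5,Takatsu et al. 1998
LBA4404,0.1,660,3,20,-,-,-,-,250,-,-,1.3-3.1,Young et al.
LBA4404,0.5,600,2,25,-,-,-,-,250,-,-,6.4%,Shao et al.
C58; MP90,0.5,600,2,50,-,-,-,-,250,-,-,1.12-1.91,Takatsu et al. 2000
EHA101,0.2,600,3,-,-,-,20-30,-,250,-,-,3.4,Shinoyama et al. 2004
EHA101,0.5,600,3,-,10-40,-,-,-,-,500,-,0-2.5,Shirasawa et al.
EHA101,1.8,660,2,100,-,-,-,125,500,-,-,0-2.3,Tosca et al.
AGL0,0.7-1,540,2,25,-,-,-,-,125,-,100,0-6.8,Annadana et al.
EHA105,2,600,2,50,-,-,-,-,-,500,-,3.4-11.4,Zhi-Liang et al.
LBA4404; AGL0,0.2,600,3,12.5,-,-,-,-,250,-,-,0.5-4.7,Ishida et al.
LBA4404,0.5,600,3,50,-,-,-,-,500,-,-,1.2-9.4,Jeong et al.
EHA101; LBA4404; AGL0,0.1,600,4,50,-,-,-,-,-,-,200,3.4-5.9,Kudo et al.
LBA4404,0.1,600,2,-,-,-,20,-,250,-,-,0-23.9,Shinoyama et al. 2006
LBA4404; AGL0,0.6,550,3-4,30,-,-,-,-,500,-,-,0-25,Teixeira da Silva and Fukai
LBA4404; AGL0,0.1,600,-,12.5,-,-,-,-,250,-,-,27-38,Toguri et al.
AGL0,0.7-1,540,4,10,-,-,-,400,250,-,-,31-39,Petty et al.
AGL0,0.8,550,6,25,-,-,-,500,250,-,-,4.7-13.4,Outchkourov et al.
EHA105; AGL0,0.1,660,8,-,-,50,-,-,250,-,-,0.5-6.5,Aida et al. 2004
EHA105,0.1,660,5,-,-,50,-,-,250,-,-,0.5-6.8,Aida et al. 2005
EHA105,0.1,660,4,-,-,50,-,-,250,-,-,0-0.6,Aida et al. 2008
EHA105,0.1,660,3,50,-,-,20,-,250,-,-,37,Shinoyama et al. 2008
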