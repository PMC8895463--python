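foodb_id,cas,name,mw,alogp,hba,hbd,pred_index,lit_ic50,lit_class
FDB022708,52-53-9,verapamil,455.6,4.0,5,0,0.93,2,potent
FDB016335,961-29-5,isoliquiritigenin,256.3,2.8,4,3,0.92,14.51,potent
FDB000449,94-62-2,piperine,285.3,2.8,3,0,0.91,17,potent
FDB000444,25924-78-1,piperyline,271.3,2.3,3,0,0.89,3.6,potent
FDB011523,485-61-0,graveoline,279.3,3.8,3,0,0.89,,
FDB015236,342371-98-6,pipercyclobutanamide B,596.7,5.2,6,0,0.89,,
FDB015235,479068-69-4,pipercyclobutanamide A,570.7,4.7,6,0,0.88,,
FDB020288,500757-86-8,dipiperamide E,570.7,4.7,6,0,0.88,0.63,potent
FDB000678,480-41-1,naringenin,272.3,2.3,5,3,0.87,8.8,potent
FDB011479,6035-40-1,gnoscopine,413.4,3.0,7,0,0.87,,
FDB016658,1668-33-3,demethoxykanugin,326.3,3.6,6,0,0.87,,
FDB018430,112448-63-2,5-methoxyhinokinin,384.4,3.6,7,0,0.86,,
FDB020287,500757-85-7,dipiperamide D,596.7,5.2,6,0,0.86,0.79,potent
FDB018555,69239-53-8,5-geranyloxy-8-methoxy-psoralen,368.4,5.3,5,0,0.86,,
FDB012066,23512-46-1,piperanine,287.4,3.2,3,0,0.86,,
FDB011280,101751-72-8,isoyatein,400.4,3.8,7,0,0.85,,
FDB014637,751-03-1,obacunone,454.5,2.1,7,0,0.85,20.9,potent
FDB011672,94-59-7,safrole,162.2,2.6,2,0,0.84,>100,weak
FDB019057,432041-19-5,dipiperamide A,570.7,4.8,6,0,0.84,0.18,potent
FDB003977,2543-94-4,phellopterin,300.3,3.5,5,0,0.83,1,potent
FDB018269,117137-65-2,"4,5-dihydropiperyline",273.3,2.7,3,0,0.83,,
FDB011395,15358-38-0,oxonantenine,335.3,2.8,6,0,0.83,,
FDB020111,155416-22-1,simulanoquinoline,618.7,6.4,7,0,0.83,,
FDB001651,3187-53-9,anhydropisatin,296.3,3.3,5,0,0.83,,
FDB005955,477-47-4,picropodophyllin,414.4,2.1,8,1,0.83,,
FDB011580,120834-89-1,lambertine,337.4,3.2,4,0,0.82,,
FDB019058,432041-21-9,dipiperamide C,556.6,4.2,6,0,0.82,0.48,potent
FDB012402,1242-81-5,dehydroneotenone,336.3,3.3,6,0,0.82,,
FDB001446,133067-72-8,(3*R*)-sophorol,300.3,2.2,6,2,0.81,,
FDB012745,583-34-6,piperettine,311.4,3.2,3,0,0.81,,
FDB017387,93767-25-0,jangomolide,468.5,1.4,8,0,0.81,,
FDB018040,117137-67-4,brachyamide B,327.4,4.1,3,0,0.81,,
FDB012281,1006528-8,dolineone,336.3,2.7,6,0,0.81,,
FDB013402,"205,115-74-8",lansiumarin B,370.4,4.1,6,1,0.81,,
FDB005049,1180-71-8,limonin,470.5,0.9,8,0,0.81,19.1,potent
FDB002789,521-32-4,bilobetin,552.5,6.1,10,5,0.81,,
FDB001536,2196-14-7,"7,4′-dihydroxyflavone",254.2,3.3,4,2,0.81,,
FDB015348,107534-93-0,macelignan,328.4,5.2,4,1,0.81,>100,weak
FDB020938,154490-59-2,"1,2-dimethoxy-13-methyl-[1,3]benzodioxolo[5,6-*c*]phenanthridine",347.4,3.9,5,0,0.80,,
FDB011383,36285-03-7,dehydroaporheine,277.3,3.7,2,0,0.80,,
FDB014514,1063-77-0,nomilin,514.6,1.6,9,0,0.80,10.4,potent
FDB018057,12751-00-7,cicerin,330.3,2.2,7,2,0.80,,
FDB014460,101560-02-5,dukunolide D,468.5,1.4,8,2,0.80,,
FDB011902,481-46-9,ginkgetin,566.5,6.3,10,4,0.80,,
FDB021029,159465-79-9,8-methyldihydrochelerythrine,363.4,4.3,4,0,0.80,,
FDB012143,548-19-6,isoginkgetin,566.5,6.3,10,4,0.80,,
FDB014461,101559-97-1,dukunolide E,484.5,0.2,9,2,0.79,,
FDB002651,60132-69-6,betagarin,328.3,2.8,6,0,0.79,,
FDB018039,117137-68-5,"(2E,4E,8E)-piperamide-C9:3",325.4,3.7,3,0,0.79,4.2,potent
FDB002766,480-44-4,acacetin,284.3,3.3,5,2,0.79,1.2,potent
FDB006932,437-64-9,genkwanin,284.3,3.3,5,2,0.79,,
FDB002709,28768-44-7,(+)-12α-hydroxypachyrrhizone,382.3,2.0,8,1,0.79,,
FDB020627,107584-38-3,dehydropipernonaline,339.4,4.1,3,0,0.79,,
FDB017322,77053-35-1,5′-methoxybilobetin,582.5,6.1,11,5,0.78,,
FDB013739,20086-05-9,diosbulbin A,376.4,0.5,7,1,0.78,,
FDB018042,112448-68-7,"(2E,6E)-piperamide-C7:2",299.4,3.2,3,0,0.78,,
FDB014182,223558-40-5,vitisifuran B,904.9,11.0,12,9,0.78,,
FDB018566,105866-30-6,epoxybergamottin,354.4,4.1,5,0,0.77,1.5,potent
FDB000586,3736-83-2,erosnin,320.3,3.3,6,0,0.77,,
FDB013340,223591-28-4,vitisifuran A,904.9,10.9,12,10,0.77,,
FDB003953,482-45-1,isoimperatorin,270.3,3.5,4,0,0.77,2.7,potent
FDB015532,90–29-9,pseudobaptigenin,282.2,2.9,5,1,0.77,,
FDB015547,14348-21-1,cnidicin,354.4,5.0,5,0,0.77,,
FDB014654,607-91-0,myristicin,192.2,2.6,3,0,0.76,43.2,weak
FDB001853,1009344-00-6,kuguacin B,418.5,3.8,4,1,0.76,,
FDB006431,482-48-4,isobergapten,216.2,2.1,4,0,0.76,>100,weak
FDB001777,23740-25-2,oxoxylopine,305.3,2.9,5,0,0.76,,
FDB019861,267428-36-4,paradisin C,726.8,8.0,11,2,0.76,1,potent
FDB011388,70560-83-8,isodomesticine,325.4,3.1,4,1,0.76,,
FDB014401,3264-90-2,deacetylnomilin,472.5,1.3,8,1,0.75,63.2,weak
FDB019053,1240562-92-8,argenteane,654.8,10.0,8,2,0.75,,
FDB011478,521-40-4,narcotoline,399.4,2.8,7,1,0.75,,
FDB011746,223591-26-2,viniferifuran,452.5,6.0,6,5,0.75,,
FDB000714,131-12-4,pimpinellidine,246.2,2.1,5,0,0.75,,
FDB019556,37687-34-6,xi-8-acetonyldihydrosanguinarine,389.4,3.4,5,0,0.75,,
FDB018295,101140-06-1,"3,8″-biapigenin",538.5,5.8,10,6,0.75,0.082,potent
FDB097289,"84,870-54-2",gnetin C,454.5,5.5,6,5,0.75,,
FDB023165,2086-83-1,berberine,336.4,3.7,4,0,0.75,48.9,weak
FDB001445,21495-84-1,2-hydroxypseudobaptigenin,298.2,2.7,6,2,0.74,,
FDB097354,153-18-4,rutin,678.7,8.6,8,7,0.74,45,weak
FDB012178,259244-41-2,isopiperolein B,343.5,4.7,3,0,0.74,,
FDB016343,60857-34-3,"2,3-dihydro-5,5′,7,7′-tetrahydroxy-2-(4-hydroxyphenyl)[3,8′-bi-4*H*-1-benzopyran]-4,4′-dione",448.4,3.3,9,5,0.74,,
FDB002183,30505-89-6,piperolein B,343.5,4.7,3,0,0.74,1.4,potent
FDB002417,520-30-9,norartocarpetin,286.2,2.8,6,4,0.73,,
FDB013637,989-23-1,desoxylimonin,454.5,1.7,7,0,0.73,,
FDB016542,107585-75-1,dihydroeucomin,316.3,2.6,6,3,0.73,,
FDB021208,165883-77-2,r-viniferin,906.9,10.5,12,9,0.73,,
FDB016339,51828-10-5,2′-methylisoliquiritigenin,270.3,3.0,4,2,0.73,,
FDB018041,62510-52-5,tricholein,329.4,4.3,3,0,0.73,2.8,potent
FDB002688,28617-71-2,13α-hydroxydolineone,352.3,2.1,7,1,0.73,,
FDB000319,62218-13-7,δ-viniferin,454.5,5.5,6,5,0.73,,
FDB019636,462636-73-3,gnemonol A,696.7,7.6,10,8,0.73,,
FDB015723,67567-13-9,diosbulbin H,418.5,1.7,7,1,0.73,,
FDB010679,75022-26-3,dihydroretrofractamide B,357.5,5.6,3,1,0.72,,
FDB022660,3735-01-1,aminoparathion,261.3,2.6,3,1,0.72,,
FDB013871,111004-32-1,isocyclocalamin,502.6,0.9,9,1,0.72,,
FDB093560,16851-21-1,morelloflavone,556.5,4.8,11,7,0.72,,
FDB015548,2035-15-6,maackiain,284.3,2.4,5,1,0.72,52.91,weak
FDB013403,205115-73-7,lansiumarin A,352.4,4.3,5,0,0.72,,
FDB011386,2466-42-4,neolitsine,323.3,3.1,4,0,0.72,,
FDB002141,517-66-8,dicentrine,339.4,3.3,4,0,0.72,,
FDB016352,16266-97-0,"3,5,6-trimethoxyflavone",312.3,3.8,5,0,0.72,,
FDB000610,480-43-3,isosakuranetin,286.3,2.5,5,2,0.71,4.3,potent
FDB011387,41787-55-7,cryptodorine,309.3,2.6,4,0,0.71,,
FDB000082,487-52-5,butein,272.3,2.5,5,4,0.71,,
FDB014643,74751-39-6,cyclocalamin,502.6,0.9,9,1,0.71,,
FDB015719,20086-06-0,diosbulbin B,344.4,0.9,6,0,0.71,,
FDB012616,530-22-3,egonol,326.3,3.8,5,1,0.71,,
FDB011341,168037-22-7,miyabenol C,680.7,8.0,9,7,0.71,,
FDB001472,2957-21-3,sakuranetin,286.3,2.5,5,2,0.71,<10,potent
FDB011998,1983-72-8,medicagol,296.2,2.9,6,1,0.71,,
FDB019458,485794-76-1,pipertipine,329.4,4.3,3,0,0.71,,
FDB014215,313485-83-5,ginsenoyne N,462.7,8.6,2,0,0.71,,
FDB001753,20979-50-4,"7,4’-dimethoxyflavone",282.3,3.8,4,0,0.71,,
FDB011382,5890-28-8,cassythicine,325.4,3.1,4,1,0.70,,
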